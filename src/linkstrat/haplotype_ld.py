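"""Founder haplotype frequencies between the disease locus A and an
associated marker, parameterised by allele frequencies and D'.

Only the single (locus A, LD marker) pair carries disequilibrium; all
other founder loci are sampled independently.  Orientation is fixed:
marker allele 1 is the associated allele, so D >= 0 when d_prime >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HaplotypeFrequencies", "build_haplotypes", "ld_summaries", "LDError"]


class LDError(ValueError):
    """Requested LD parameters are impossible or undefined."""


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """2x2 haplotype table over (disease allele, marker allele).

    ``freqs[i, j]``: row 0 = disease allele (allele 1 at A), row 1 = normal
    allele; column 0 = marker allele 1 (associated), column 1 = allele 2.
    """

    freqs: np.ndarray
    p_disease: float
    p_marker1: float
    d: float
    d_prime: float
    r2: float

    def conditional_marker1(self) -> tuple[float, float]:
        """P(marker allele 1 | disease allele), P(marker allele 1 | normal)."""
        f = self.freqs
        return (
            float(f[0, 0] / (self.p_disease or np.nan)),
            float(f[1, 0] / ((1.0 - self.p_disease) or np.nan)),
        )


def build_haplotypes(
    p_disease: float, p_marker1: float, d_prime: float
) -> HaplotypeFrequencies:
    """Construct the haplotype table from marginals and D' in [0, 1].

    D = D' * Dmax with Dmax = min(p_disease * (1 - p_marker1),
    (1 - p_disease) * p_marker1); freq(disease, allele1) =
    p_disease * p_marker1 + D, remaining cells by the marginal constraints.
    """
    if not (0.0 < p_disease < 1.0 and 0.0 < p_marker1 < 1.0):
        raise LDError("allele frequencies must be in (0, 1)")
    if not 0.0 <= d_prime <= 1.0:
        raise LDError("d_prime must be in [0, 1] (allele 1 is the associated allele)")
    dmax = min(p_disease * (1.0 - p_marker1), (1.0 - p_disease) * p_marker1)
    d = d_prime * dmax
    f11 = p_disease * p_marker1 + d
    freqs = np.array(
        [
            [f11, p_disease - f11],
            [p_marker1 - f11, 1.0 - p_disease - p_marker1 + f11],
        ]
    )
    if (freqs < -1e-12).any():
        raise LDError(
            f"impossible haplotype table for pA={p_disease}, "
            f"p1={p_marker1}, D'={d_prime}"
        )
    freqs = np.clip(freqs, 0.0, 1.0)
    _, dp, r2 = ld_summaries(freqs)
    return HaplotypeFrequencies(
        freqs=freqs,
        p_disease=p_disease,
        p_marker1=p_marker1,
        d=float(d),
        d_prime=float(dp),
        r2=float(r2),
    )


def ld_summaries(freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) for a 2x2 haplotype frequency table.

    D = f11 - pA*p1; D' = D / Dmax with the sign-appropriate Dmax;
    r^2 = D^2 / (pA(1-pA) p1(1-p1)).
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (2, 2):
        raise LDError("haplotype table must be 2x2")
    if abs(f.sum() - 1.0) > 1e-9 or (f < -1e-12).any():
        raise LDError("haplotype frequencies must be non-negative and sum to 1")
    pa = f[0].sum()
    p1 = f[:, 0].sum()
    if pa <= 0 or pa >= 1 or p1 <= 0 or p1 >= 1:
        raise LDError("LD undefined: degenerate marginal allele frequency")
    d = f[0, 0] - pa * p1
    if d >= 0:
        dmax = min(pa * (1.0 - p1), (1.0 - pa) * p1)
    else:
        dmax = min(pa * p1, (1.0 - pa) * (1.0 - p1))
    dprime = 0.0 if dmax == 0 else d / dmax
    r2 = d * d / (pa * (1.0 - pa) * p1 * (1.0 - p1))
    return float(d), float(dprime), float(r2)
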