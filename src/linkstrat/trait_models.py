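"""Two-locus trait models: epistatic and heterogeneity architectures.

Epistasis here means the disease genotype must be present at *both* loci
for disease expression; within that requirement the penetrance is full
(1.0) by default.  The four epistatic models are named by the mode of
inheritance at locus A then locus B: DD, DR, RD, RR.  Disease-causing
genotype sets (capital letter = disease allele):

    DD: AABB, AABb, AaBB, AaBb
    DR: AABB, AaBB
    RD: AABB, AABb
    RR: AABB

Genetic heterogeneity is the non-interacting counterpart: either locus
alone can independently cause disease, each with per-locus penetrance 0.5
(models D+D, D+R, R+D, R+R).  Under the default "union" rule causation is
resolved per individual: P(affected) = 1 - (1 - f*I_A)(1 - f*I_B) where
I_X indicates the disease genotype at locus X.  An alternative "admixture"
rule (each family assigned a single causal locus) is available because
either reading is defensible; see docs/methods.md.

Disease allele frequencies follow the study conditions: 0.1 when the mode
at a locus is dominant, 0.2 when recessive.  Phenocopy rates are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoLocusTraitModel",
    "MODEL_NAMES",
    "from_name",
    "is_disease_genotype",
    "penetrance",
    "penetrance_from_counts",
    "prevalence",
    "DOMINANT_FREQ",
    "RECESSIVE_FREQ",
]

DOMINANT_FREQ = 0.1
RECESSIVE_FREQ = 0.2

MODEL_NAMES = ("DD", "DR", "RD", "RR", "D+D", "D+R", "R+D", "R+R")


@dataclass(frozen=True)
class TwoLocusTraitModel:
    architecture: str  # "epistatic" | "heterogeneity"
    mode_A: str  # "dominant" | "recessive"
    mode_B: str
    freq_A: float
    freq_B: float
    locus_penetrance: float  # joint (epistasis) or per-locus (heterogeneity)
    het_rule: str = "union"  # "union" | "admixture"
    name: str = ""

    def __post_init__(self):
        if self.architecture not in ("epistatic", "heterogeneity"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        for mode in (self.mode_A, self.mode_B):
            if mode not in ("dominant", "recessive"):
                raise ValueError(f"unknown mode {mode!r}")
        for f in (self.freq_A, self.freq_B):
            if not 0.0 < f < 1.0:
                raise ValueError("disease allele frequencies must be in (0, 1)")
        if not 0.0 <= self.locus_penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if self.het_rule not in ("union", "admixture"):
            raise ValueError(f"unknown heterogeneity rule {self.het_rule!r}")


def _mode_freq(letter: str) -> tuple[str, float]:
    if letter == "D":
        return "dominant", DOMINANT_FREQ
    if letter == "R":
        return "recessive", RECESSIVE_FREQ
    raise ValueError(f"unknown mode letter {letter!r}")


def from_name(name: str, het_rule: str = "union") -> TwoLocusTraitModel:
    """Build a model from its short name (DD, DR, RD, RR, D+D, D+R, R+D, R+R)."""
    name = name.strip().upper()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    if "+" in name:
        a, b = name.split("+")
        architecture, pen = "heterogeneity", 0.5
    else:
        a, b = name[0], name[1]
        architecture, pen = "epistatic", 1.0
    mode_a, freq_a = _mode_freq(a)
    mode_b, freq_b = _mode_freq(b)
    return TwoLocusTraitModel(
        architecture=architecture,
        mode_A=mode_a,
        mode_B=mode_b,
        freq_A=freq_a,
        freq_B=freq_b,
        locus_penetrance=pen,
        het_rule=het_rule,
        name=name,
    )


def is_disease_genotype(mode: str, genotype) -> bool:
    """Whether a single-locus genotype is disease-causing under ``mode``.

    ``genotype`` is a pair of allele codes where allele 1 is the disease
    allele.  Dominant: at least one disease allele; recessive: two.
    """
    count = int(genotype[0] == 1) + int(genotype[1] == 1)
    return count >= 1 if mode == "dominant" else count == 2


def _indicator_from_counts(mode: str, counts: np.ndarray) -> np.ndarray:
    return (counts >= 1) if mode == "dominant" else (counts == 2)


def penetrance_from_counts(
    model: TwoLocusTraitModel, count_A, count_B
) -> np.ndarray:
    """Vectorised penetrance from disease-allele counts at the two loci."""
    ia = _indicator_from_counts(model.mode_A, np.asarray(count_A))
    ib = _indicator_from_counts(model.mode_B, np.asarray(count_B))
    f = model.locus_penetrance
    if model.architecture == "epistatic":
        return f * (ia & ib)
    # heterogeneity (union rule): independent causal draws per locus
    return 1.0 - (1.0 - f * ia) * (1.0 - f * ib)


def penetrance(model: TwoLocusTraitModel, geno_A, geno_B) -> float:
    """Probability of affection given ordered/unordered genotypes at A and B."""
    ca = int(geno_A[0] == 1) + int(geno_A[1] == 1)
    cb = int(geno_B[0] == 1) + int(geno_B[1] == 1)
    return float(penetrance_from_counts(model, ca, cb))


def _hw_genotype_probs(q: float) -> np.ndarray:
    """P(0, 1, 2 disease alleles) under Hardy-Weinberg at frequency q."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def prevalence(model: TwoLocusTraitModel) -> float:
    """Population prevalence under Hardy-Weinberg and random mating.

    Under the admixture heterogeneity rule the causal locus is assigned per
    family with probability 1/2 each, so the population prevalence is the
    average of the two single-locus prevalences.
    """
    pa = _hw_genotype_probs(model.freq_A)
    pb = _hw_genotype_probs(model.freq_B)
    counts = np.arange(3)
    ia = _indicator_from_counts(model.mode_A, counts).astype(float)
    ib = _indicator_from_counts(model.mode_B, counts).astype(float)
    f = model.locus_penetrance
    if model.architecture == "epistatic":
        return float(f * (pa @ ia) * (pb @ ib))
    if model.het_rule == "admixture":
        return float(0.5 * f * (pa @ ia) + 0.5 * f * (pb @ ib))
    qa, qb = f * (pa @ ia), f * (pb @ ib)
    return float(1.0 - (1.0 - qa) * (1.0 - qb))
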