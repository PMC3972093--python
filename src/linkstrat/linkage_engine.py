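"""Exact parametric multipoint lod scores for nuclear families.

The engine is a hidden-Markov model over inheritance vectors: for a
family with n offspring the hidden state at each locus records, for every
offspring, which paternal and which maternal haplotype was transmitted
(2 bits per offspring, 4**n states).  Between adjacent loci each bit
flips independently with probability theta (Haldane model, no
interference).  Marker emissions marginalise the four founder ordered
genotypes per locus against observed (phase-unknown) genotypes; the
disease-locus phenotype factor marginalises founder disease genotypes
under Hardy-Weinberg at the analysis allele frequency, with a penetrance
vector over disease-allele counts.

Siblings with identical observed data (same unordered genotype at every
informative marker and same affection status) are exchangeable: all
emission and phenotype factors are symmetric under permuting them.  The
state space is therefore collapsed, exactly, from the 4**n inheritance
vectors to the product over sibling groups of count multisets -- a group
of k identical sibs contributes C(k+3, 3) states instead of 4**k.  With
dense maps and moderate sibship sizes this routinely shrinks the state
space by orders of magnitude while leaving every probability unchanged.

The lod at a test position x is

    lod(x) = sum over families log10 [ P(phenotypes, markers | disease at x)
                                       / (P(markers) * P(phenotypes)) ]

where P(phenotypes) is the segregation likelihood with the disease locus
unlinked to all markers.  Conditioning on the inheritance vector at x
renders phenotypes and markers independent, so the numerator is an inner
product of the marker forward/backward distributions at x with the
phenotype factor.

A brute-force likelihood (`elston_stewart_loglik`) that sums explicitly
over founder multilocus ordered genotypes and offspring transmission
patterns serves as an independent oracle for small families; it shares no
code with the HMM path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache, reduce
from math import factorial

import numpy as np

from .pedigree import (
    GeneticMap,
    MISSING,
    Pedigree,
    haldane_cm,
    inverse_haldane,
)
from .trait_models import TwoLocusTraitModel

__all__ = [
    "AnalysisModel",
    "LodCurve",
    "MendelianError",
    "FamilyTooLargeError",
    "multipoint_lod",
    "max_lod_in_interval",
    "b_interval_grid",
    "elston_stewart_loglik",
    "elston_stewart_lod",
]

MAX_OFFSPRING_EXACT = 10


class MendelianError(ValueError):
    """Observed genotypes are impossible given the pedigree structure."""


class FamilyTooLargeError(ValueError):
    """Family exceeds the exact computation limit."""


@dataclass(frozen=True)
class AnalysisModel:
    """Single-locus analysis model for the test (disease) locus.

    The penetrance vector over 0/1/2 disease-allele counts is
    (phenocopy, f, f) for a dominant model and (phenocopy, phenocopy, f)
    for a recessive one, where f is the carrier penetrance (0.5 by
    default, the reduced penetrance induced at the test locus by an
    unmodelled interacting partner).
    """

    mode: str
    disease_allele_freq: float
    penetrance_carrier: float = 0.5
    phenocopy_rate: float = 0.0

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("analysis allele frequency must be in (0, 1)")

    @property
    def penetrance_vector(self) -> np.ndarray:
        f, p = self.penetrance_carrier, self.phenocopy_rate
        if self.mode == "dominant":
            return np.array([p, f, f])
        return np.array([p, p, f])

    @classmethod
    def matched_to_B(cls, trait: TwoLocusTraitModel,
                     penetrance_carrier: float = 0.5) -> "AnalysisModel":
        """Analysis model matched to the generating values at locus B."""
        return cls(
            mode=trait.mode_B,
            disease_allele_freq=trait.freq_B,
            penetrance_carrier=penetrance_carrier,
        )


@dataclass
class LodCurve:
    """Multipoint lod values over map positions (Morgans, full-map
    coordinates); ``per_family`` rows are family contributions."""

    positions: np.ndarray
    lod: np.ndarray
    per_family: np.ndarray | None = None


def max_lod_in_interval(
    curve: LodCurve, lo: float = -np.inf, hi: float = np.inf
) -> tuple[float, float]:
    """(position, max lod) over evaluated positions within [lo, hi]."""
    mask = (curve.positions >= lo) & (curve.positions <= hi)
    if not mask.any():
        raise ValueError("no evaluated positions in the requested interval")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(curve.lod[idx])]
    return float(curve.positions[best]), float(curve.lod[best])


def b_interval_grid(gmap: GeneticMap, n_interior: int = 4) -> np.ndarray:
    """Evaluation grid for the linkage interval containing locus B:
    both flanking markers, locus B's own position, and ``n_interior``
    equally spaced points inside each sub-interval."""
    pos = gmap.positions()
    left = max(i for i in gmap.marker_indices if i < gmap.index_B)
    right = min(i for i in gmap.marker_indices if i > gmap.index_B)
    a, m, b = pos[left], pos[gmap.index_B], pos[right]
    grid = np.concatenate(
        [np.linspace(a, m, n_interior + 2), np.linspace(m, b, n_interior + 2)]
    )
    return np.unique(grid)


# ---------------------------------------------------------------------------
# marker view of a map: disease loci are unobserved, so the analysis runs on
# markers only, with recombination composed across the skipped positions
# ---------------------------------------------------------------------------

@dataclass
class _MarkerView:
    freqs1: np.ndarray  # allele-1 frequency per marker
    theta: np.ndarray  # inter-marker recombination fractions
    coords: np.ndarray  # cumulative Haldane positions (full-map coords)
    orig: list[int]  # original locus indices


def _marker_view(gmap: GeneticMap) -> _MarkerView:
    idx = gmap.marker_indices
    pos = gmap.positions()
    theta = np.array(
        [gmap.compound_theta(idx[k], idx[k + 1]) for k in range(len(idx) - 1)]
    )
    return _MarkerView(
        freqs1=np.array([gmap.loci[i].allele_freqs[0] for i in idx]),
        theta=theta,
        coords=pos[idx],
        orig=idx,
    )


def _locate(view: _MarkerView, p: float) -> tuple[int, float, float]:
    """Map a Morgan coordinate to (interval index, theta_left, theta_right)."""
    c = view.coords
    if p < c[0] - 1e-12 or p > c[-1] + 1e-12:
        raise ValueError("position outside the marker map")
    i = int(np.searchsorted(c, p, side="right") - 1)
    i = min(max(i, 0), len(c) - 2)
    tl = inverse_haldane(max(p - c[i], 0.0))
    tr = inverse_haldane(max(c[i + 1] - p, 0.0))
    return i, tl, tr


# ---------------------------------------------------------------------------
# grouped inheritance-vector HMM
# ---------------------------------------------------------------------------

# the 16 ordered founder-couple allele configurations at one locus:
# (father hap1, father hap2, mother hap1, mother hap2), alleles coded 1/2
_CONFIGS = np.array(
    [[a, b, c, d] for a in (1, 2) for b in (1, 2) for c in (1, 2) for d in (1, 2)],
    dtype=np.int8,
)
# child allele pair for each of the 4 per-offspring inheritance values
# j = 2*paternal_bit + maternal_bit
_CHILD_P = np.stack([_CONFIGS[:, 0], _CONFIGS[:, 0], _CONFIGS[:, 1], _CONFIGS[:, 1]], 1)
_CHILD_M = np.stack([_CONFIGS[:, 2], _CONFIGS[:, 3], _CONFIGS[:, 2], _CONFIGS[:, 3]], 1)
_CHILD_LO = np.minimum(_CHILD_P, _CHILD_M)  # (16, 4)
_CHILD_HI = np.maximum(_CHILD_P, _CHILD_M)


@lru_cache(maxsize=32)
def _compositions(k: int):
    """All (m0, m1, m2, m3) with sum k, their index map, and multinomial
    multiplicities k!/(m0! m1! m2! m3!)."""
    comps = []
    for m0 in range(k + 1):
        for m1 in range(k + 1 - m0):
            for m2 in range(k + 1 - m0 - m1):
                comps.append((m0, m1, m2, k - m0 - m1 - m2))
    index = {m: i for i, m in enumerate(comps)}
    mult = np.array(
        [
            factorial(k)
            // (factorial(a) * factorial(b) * factorial(c) * factorial(d))
            for a, b, c, d in comps
        ],
        dtype=float,
    )
    return tuple(comps), index, mult


def _k2_kernel(theta: float) -> np.ndarray:
    return np.array([[1 - theta, theta], [theta, 1 - theta]])


@lru_cache(maxsize=512)
def _group_transition(k: int, theta: float) -> np.ndarray:
    """Transition matrix on count multisets for k exchangeable siblings.

    Row-stochastic: entry [m, m'] is the probability that k sibs with
    inheritance-value counts m end up with counts m' after each flips its
    paternal and maternal bits independently with probability theta.
    Built by adding one sibling at a time to the (k-1)-sib matrix.
    """
    k4 = np.kron(_k2_kernel(theta), _k2_kernel(theta))
    if k == 1:
        return k4
    comps, index, _ = _compositions(k)
    comps_prev, index_prev, _ = _compositions(k - 1)
    t_prev = _group_transition(k - 1, theta)
    # index of m'_prev + e_j within the k-sib composition list
    lift = np.empty((4, len(comps_prev)), dtype=np.intp)
    for j in range(4):
        for i, m in enumerate(comps_prev):
            mm = list(m)
            mm[j] += 1
            lift[j, i] = index[tuple(mm)]
    out = np.zeros((len(comps), len(comps)))
    for mi, m in enumerate(comps):
        j = next(a for a in range(4) if m[a] > 0)
        mm = list(m)
        mm[j] -= 1
        row_prev = t_prev[index_prev[tuple(mm)]]
        for j2 in range(4):
            np.add.at(out[mi], lift[j2], k4[j, j2] * row_prev)
    return out


def _apply_grouped(theta: float, counts: tuple[int, ...], v: np.ndarray) -> np.ndarray:
    """Apply the per-group transition along each group axis of v."""
    if theta == 0.0 or not counts:
        return v
    dims = tuple(len(_compositions(k)[0]) for k in counts)
    t = v.reshape(dims)
    for ax, k in enumerate(counts):
        tk = _group_transition(k, float(theta))
        t = np.moveaxis(np.tensordot(tk, t, axes=([1], [ax])), 0, ax)
    return t.reshape(-1)


def _group_values(e4: np.ndarray, k: int) -> np.ndarray:
    """Per-class product values for a group of k identical sibs: for each
    count multiset m, prod_j e4[j]**m[j]."""
    comps, _, _ = _compositions(k)
    comp_arr = np.array(comps)  # (d, 4)
    with np.errstate(invalid="ignore"):
        vals = np.power(e4[None, :], comp_arr).prod(axis=1)
    return vals


def _outer(parts: list[np.ndarray]) -> np.ndarray:
    out = parts[0]
    for p in parts[1:]:
        out = (out[:, None] * p[None, :]).reshape(-1)
    return out


def _extract_family(ped: Pedigree, view: _MarkerView):
    father, mother = ped.father, ped.mother
    offspring = ped.offspring
    orig = view.orig
    par = np.stack([father.genotypes[orig], mother.genotypes[orig]])  # (2, M, 2)
    off = (
        np.stack([o.genotypes[orig] for o in offspring])
        if offspring
        else np.zeros((0, len(orig), 2), dtype=np.int8)
    )
    aff = np.array(
        [father.affected, mother.affected] + [o.affected for o in offspring]
    )
    return par, off, aff


def _pair_match(obs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Match observed unordered genotypes against candidate ordered pairs.

    obs: (..., 2); lo/hi broadcastable candidate sorted pairs.  A genotype
    with any missing allele matches everything.
    """
    o_lo = np.minimum(obs[..., 0], obs[..., 1])
    o_hi = np.maximum(obs[..., 0], obs[..., 1])
    miss = (obs == MISSING).any(axis=-1)
    return np.where(miss, 1.0, ((o_lo == lo) & (o_hi == hi)).astype(float))


def _founder_config_weights(view: _MarkerView, par: np.ndarray) -> np.ndarray:
    """(n_markers, 16): founder allele priors times parent genotype match."""
    pr = np.where(
        _CONFIGS[None, :, :] == 1,
        view.freqs1[:, None, None],
        1.0 - view.freqs1[:, None, None],
    ).prod(axis=2)
    f_lo = np.minimum(_CONFIGS[:, 0], _CONFIGS[:, 1])
    f_hi = np.maximum(_CONFIGS[:, 0], _CONFIGS[:, 1])
    m_lo = np.minimum(_CONFIGS[:, 2], _CONFIGS[:, 3])
    m_hi = np.maximum(_CONFIGS[:, 2], _CONFIGS[:, 3])
    return (
        pr
        * _pair_match(par[0][:, None, :], f_lo[None, :], f_hi[None, :])
        * _pair_match(par[1][:, None, :], m_lo[None, :], m_hi[None, :])
    )


def _pheno_weight(pen: np.ndarray, count, affected: bool) -> np.ndarray:
    p = pen[count]
    return p if affected else 1.0 - p


class _GroupedFamily:
    """One nuclear family on the grouped inheritance-vector state space."""

    def __init__(
        self,
        ped: Pedigree,
        view: _MarkerView,
        seg_lo: int,
        seg_hi: int,
    ):
        self.family_id = ped.family_id
        par, off, aff = _extract_family(ped, view)
        self.aff = aff
        n = off.shape[0]
        # group offspring by (unordered genotypes on the informative
        # segment, affection); identical sibs are exchangeable
        buckets: dict = {}
        for o in range(n):
            rows = []
            for m in range(seg_lo, seg_hi + 1):
                a, b = int(off[o, m, 0]), int(off[o, m, 1])
                rows.append((0, 0) if MISSING in (a, b) else (min(a, b), max(a, b)))
            key = (tuple(rows), bool(aff[2 + o]))
            buckets.setdefault(key, []).append(o)
        self.reps = [members[0] for members in buckets.values()]
        self.counts = tuple(len(members) for members in buckets.values())
        self.dims = tuple(len(_compositions(k)[0]) for k in self.counts)
        self.n_states = int(np.prod(self.dims)) if self.dims else 1
        self.n_offspring = n
        # state multiplicities (class sizes in the original 4**n space)
        self.weights = (
            _outer([_compositions(k)[2] for k in self.counts])
            if self.counts
            else np.ones(1)
        )
        self.w16 = _founder_config_weights(view, par)  # (M, 16)
        if n:
            self.c16 = _pair_match(
                off[self.reps].transpose(1, 0, 2)[:, None, :, None, :],
                _CHILD_LO[None, :, None, :],
                _CHILD_HI[None, :, None, :],
            )  # (M, 16, n_groups, 4)
        else:
            self.c16 = None

    def emission(self, m: int) -> np.ndarray:
        """P(genotypes at marker m | grouped state), vector of n_states."""
        if self.c16 is None:
            return np.array([self.w16[m].sum()])
        out = np.zeros(self.n_states)
        for cfg in np.flatnonzero(self.w16[m] > 0.0):
            parts = [
                _group_values(self.c16[m, cfg, g], k)
                for g, k in enumerate(self.counts)
            ]
            out += self.w16[m, cfg] * _outer(parts)
        return out

    def phenotype_factor(self, analysis: AnalysisModel) -> np.ndarray:
        """P(phenotypes | grouped state at the disease locus)."""
        q = analysis.disease_allele_freq
        pen = analysis.penetrance_vector
        pr = np.where(_CONFIGS == 1, q, 1.0 - q).prod(axis=1)  # (16,)
        f_cnt = (_CONFIGS[:, :2] == 1).sum(axis=1)
        m_cnt = (_CONFIGS[:, 2:] == 1).sum(axis=1)
        w = (
            pr
            * _pheno_weight(pen, f_cnt, self.aff[0])
            * _pheno_weight(pen, m_cnt, self.aff[1])
        )
        child_cnt = (_CHILD_P == 1).astype(int) + (_CHILD_M == 1).astype(int)
        if not self.counts:
            return np.array([w.sum()])
        phi = np.zeros(self.n_states)
        for cfg in np.flatnonzero(w > 0.0):
            parts = [
                _group_values(
                    _pheno_weight(pen, child_cnt[cfg], self.aff[2 + self.reps[g]]),
                    k,
                )
                for g, k in enumerate(self.counts)
            ]
            phi += w[cfg] * _outer(parts)
        return phi


def _family_lods(
    ped: Pedigree,
    view: _MarkerView,
    analysis: AnalysisModel,
    located: list[tuple[int, float, float]],
) -> np.ndarray:
    """lod contributions of one family at the located positions."""
    n = len(ped.offspring)
    if n > MAX_OFFSPRING_EXACT:
        raise FamilyTooLargeError(
            f"family {ped.family_id}: {n} offspring exceeds the exact limit "
            f"of {MAX_OFFSPRING_EXACT}"
        )
    M = len(view.freqs1)
    need_f = {i for i, _, _ in located}
    need_r = {i + 1 for i, _, _ in located}
    # markers separated from every evaluated position by a free-recombination
    # gap (theta = 0.5) carry no information about the inheritance vector
    # there, and their likelihood factor cancels in the lod ratio: restrict
    # the sweep to the linked marker segment containing the positions.
    gaps = [k for k in range(M - 1) if view.theta[k] >= 0.5]
    seg_lo, seg_hi = 0, M - 1
    for g in gaps:
        if g < min(need_f):
            seg_lo = max(seg_lo, g + 1)
        if g >= max(need_r):
            seg_hi = min(seg_hi, g)

    fam = _GroupedFamily(ped, view, seg_lo, seg_hi)
    counts = fam.counts
    phi = fam.phenotype_factor(analysis)
    wts = fam.weights
    mean_phi = float((wts * phi).sum() / wts.sum())

    def step(v: np.ndarray, theta: float, m: int) -> np.ndarray:
        v = fam.emission(m) * _apply_grouped(theta, counts, v)
        z = v.sum()
        if z == 0.0:
            raise MendelianError(
                f"family {ped.family_id}: inconsistent genotypes"
            )
        return v / z

    # forward (normalised; scale factors cancel in the lod ratios)
    fstore: dict[int, np.ndarray] = {}
    f = fam.emission(seg_lo)
    if f.sum() == 0.0:
        raise MendelianError(f"family {ped.family_id}: inconsistent genotypes")
    f = f / f.sum()
    if seg_lo in need_f:
        fstore[seg_lo] = f
    for m in range(seg_lo + 1, max(need_f) + 1):
        f = step(f, view.theta[m - 1], m)
        if m in need_f:
            fstore[m] = f
    rstore: dict[int, np.ndarray] = {}
    r = fam.emission(seg_hi)
    if r.sum() == 0.0:
        raise MendelianError(f"family {ped.family_id}: inconsistent genotypes")
    r = r / r.sum()
    if seg_hi in need_r:
        rstore[seg_hi] = r
    for m in range(seg_hi - 1, min(need_r) - 1, -1):
        r = step(r, view.theta[m], m)
        if m in need_r:
            rstore[m] = r

    lods = np.empty(len(located))
    for k, (i, tl, tr) in enumerate(located):
        u = (
            wts
            * _apply_grouped(tl, counts, fstore[i])
            * _apply_grouped(tr, counts, rstore[i + 1])
        )
        pm = float(u.sum())
        num = float((u * phi).sum())
        lods[k] = np.log10(num) - np.log10(pm) - np.log10(mean_phi)
    return lods


def multipoint_lod(
    pedigrees: list[Pedigree],
    gmap: GeneticMap,
    analysis_model: AnalysisModel,
    positions: np.ndarray | None = None,
    keep_per_family: bool = False,
) -> LodCurve:
    """Total multipoint lod curve over the given map positions (Morgans).

    Only marker genotypes and affection are used; the disease loci on the
    map are treated as unobserved.  Positions default to the evaluation
    grid of the linkage interval containing locus B.  The dataset lod is
    the sum of the per-family lods (the likelihood factorises over
    families).
    """
    if positions is None:
        positions = b_interval_grid(gmap)
    positions = np.asarray(positions, dtype=float)
    view = _marker_view(gmap)
    located = [_locate(view, p) for p in positions]
    per_family = np.zeros((len(pedigrees), len(positions)))
    for k, ped in enumerate(pedigrees):
        per_family[k] = _family_lods(ped, view, analysis_model, located)
    return LodCurve(
        positions=positions,
        lod=per_family.sum(axis=0),
        per_family=per_family if keep_per_family else None,
    )


# ---------------------------------------------------------------------------
# brute-force oracle: explicit summation over founder multilocus ordered
# genotypes and offspring transmission patterns
# ---------------------------------------------------------------------------

ORACLE_MAX_LOCI = 6
ORACLE_MAX_OFFSPRING = 4


def _bit_matrix(L: int) -> np.ndarray:
    p = np.arange(2**L)
    return np.stack([(p >> l) & 1 for l in range(L)], axis=1).astype(np.int8)


def _enumerate_likelihood(
    freqs1: np.ndarray,
    thetas: np.ndarray,
    emit: np.ndarray,
) -> float:
    """P(all observations) for one nuclear family by full enumeration.

    ``emit[k, l, a, b]`` is the emission weight of member k (0 = father,
    1 = mother, then offspring) at locus l for the ordered allele pair
    with 0-based codes (a, b); marker match and phenotype-penetrance
    weights have already been folded in by the caller.
    """
    n_mem, L = emit.shape[:2]
    H = _bit_matrix(L)  # (2**L, L) 0-based allele codes
    nh = H.shape[0]
    hap_w = np.where(H == 0, freqs1, 1.0 - freqs1).prod(axis=1)  # (2**L,)

    def founder_w(k: int) -> np.ndarray:
        wf = hap_w[:, None] * hap_w[None, :]
        for l in range(L):
            wf = wf * emit[k, l][H[:, l][:, None], H[None, :, l]]
        return wf

    W_f, W_m = founder_w(0), founder_w(1)

    # transmission pattern weights: first locus free, then theta per interval
    P = _bit_matrix(L)
    tw = np.full(nh, 0.5)
    for l in range(1, L):
        rec = P[:, l] != P[:, l - 1]
        tw *= np.where(rec, thetas[l - 1], 1.0 - thetas[l - 1])

    # gamete alleles per (hap1, hap2, pattern, locus)
    G = np.where(
        P[None, None, :, :] == 0, H[:, None, None, :], H[None, :, None, :]
    )

    prod_T = np.ones((nh, nh, nh, nh))
    for o in range(n_mem - 2):
        T = np.zeros((nh, nh, nh, nh))
        for pp in range(nh):
            gp = G[:, :, pp, :]  # paternal gamete (h1f, h2f, L)
            for pm in range(nh):
                gm = G[:, :, pm, :]
                term = np.ones((nh, nh, nh, nh))
                for l in range(L):
                    term = term * emit[2 + o, l][
                        gp[:, :, l][:, :, None, None], gm[None, None, :, :, l]
                    ]
                T += tw[pp] * tw[pm] * term
        prod_T = prod_T * T
    return float(np.einsum("ab,cd,abcd->", W_f, W_m, prod_T))


def _oracle_emissions(
    ped: Pedigree,
    freqs1: np.ndarray,
    kinds: list[str],
    obs_idx: list[int | None],
    analysis: AnalysisModel | None,
) -> np.ndarray:
    members = [ped.father, ped.mother] + ped.offspring
    L = len(freqs1)
    emit = np.ones((len(members), L, 2, 2))
    # allele-1 (disease) count per ordered 0-based pair: code 0 is allele 1
    a0 = np.array([[2, 1], [1, 0]])
    for k, mem in enumerate(members):
        for l in range(L):
            if kinds[l] == "marker":
                g = mem.genotypes[obs_idx[l]]
                if MISSING in (int(g[0]), int(g[1])):
                    continue
                lo, hi = sorted((int(g[0]), int(g[1])))
                for a in range(2):
                    for b in range(2):
                        pair = tuple(sorted((a + 1, b + 1)))
                        emit[k, l, a, b] = 1.0 if pair == (lo, hi) else 0.0
            else:
                pen = analysis.penetrance_vector
                p = pen[a0]
                emit[k, l] = p if mem.affected else 1.0 - p
    return emit


def _oracle_loci(
    ped: Pedigree,
    gmap: GeneticMap,
    analysis: AnalysisModel | None,
    position: float | None,
):
    """Marker loci (plus the disease locus at ``position``) for enumeration."""
    view = _marker_view(gmap)
    freqs = list(view.freqs1)
    kinds = ["marker"] * len(freqs)
    obs_idx: list[int | None] = list(view.orig)  # original map locus indices
    thetas = list(view.theta)
    if position is not None:
        i, tl, tr = _locate(view, position)
        freqs.insert(i + 1, analysis.disease_allele_freq)
        kinds.insert(i + 1, "disease")
        obs_idx.insert(i + 1, None)
        thetas[i : i + 1] = [tl, tr]
    return np.array(freqs), np.array(thetas), kinds, obs_idx


def elston_stewart_loglik(
    ped: Pedigree,
    gmap: GeneticMap,
    analysis_model: AnalysisModel | None = None,
    position: float | None = None,
    include_phenotypes: bool = True,
) -> float:
    """log10 likelihood of one family's observations by brute force.

    With ``position`` given (Morgans), the disease locus is inserted there
    and phenotypes are included; with ``position=None`` only the marker
    data are evaluated.  Deliberately independent of the HMM engine.
    """
    n = len(ped.offspring)
    if n > ORACLE_MAX_OFFSPRING:
        raise FamilyTooLargeError(
            f"oracle limited to {ORACLE_MAX_OFFSPRING} offspring (got {n})"
        )
    freqs1, thetas, kinds, obs_idx = _oracle_loci(
        ped, gmap, analysis_model if include_phenotypes else None, position
    )
    if len(freqs1) > ORACLE_MAX_LOCI:
        raise FamilyTooLargeError(
            f"oracle limited to {ORACLE_MAX_LOCI} loci (got {len(freqs1)})"
        )
    emit = _oracle_emissions(ped, freqs1, kinds, obs_idx, analysis_model)
    lik = _enumerate_likelihood(freqs1, thetas, emit)
    if lik <= 0.0:
        raise MendelianError(
            f"family {ped.family_id}: zero likelihood (Mendelian inconsistency)"
        )
    return float(np.log10(lik))


def _phenotype_only_loglik(ped: Pedigree, analysis: AnalysisModel) -> float:
    """log10 segregation likelihood of the phenotypes alone (disease locus
    unlinked to any marker)."""
    q = analysis.disease_allele_freq
    pen = analysis.penetrance_vector
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])

    def w(aff, cnt):
        p = pen[cnt]
        return p if aff else 1.0 - p

    total = 0.0
    counts = np.arange(3)
    # transmission: P(child count | parent counts) for a biallelic locus
    trans = np.zeros((3, 3, 3))
    for cf in range(3):
        for cm in range(3):
            pf, pm = cf / 2.0, cm / 2.0
            trans[cf, cm] = np.array(
                [
                    (1 - pf) * (1 - pm),
                    pf * (1 - pm) + pm * (1 - pf),
                    pf * pm,
                ]
            )
    for cf in range(3):
        for cm in range(3):
            term = hw[cf] * hw[cm] * w(ped.father.affected, cf) * w(
                ped.mother.affected, cm
            )
            for o in ped.offspring:
                term *= sum(
                    trans[cf, cm, c] * w(o.affected, c) for c in counts
                )
            total += term
    return float(np.log10(total))


def elston_stewart_lod(
    ped: Pedigree,
    gmap: GeneticMap,
    analysis_model: AnalysisModel,
    position: float,
) -> float:
    """Single-family lod at one position via the brute-force oracle."""
    joint = elston_stewart_loglik(ped, gmap, analysis_model, position)
    markers = elston_stewart_loglik(ped, gmap, include_phenotypes=False)
    pheno = _phenotype_only_loglik(ped, analysis_model)
    return joint - markers - pheno
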