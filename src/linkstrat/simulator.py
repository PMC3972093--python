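"""Gene-dropping simulation of ascertained nuclear families.

Families are two-generation pedigrees: two founders whose haplotypes are
drawn from population allele frequencies (the disease-locus-A / LD-marker
pair is drawn jointly from the haplotype table, all other loci
independently), and 2-10 offspring, each receiving one recombinant gamete
per parent.  Crossovers occur independently between adjacent loci with
probability theta (Haldane model, no interference).  Affection is assigned
by the trait model's penetrance with an independent uniform draw.

Ascertainment is by rejection: a family enters a dataset only if it has at
least one affected offspring and at least four members.  Each dataset
collects a fixed number of ascertained families (50 by default); an
experiment is a set of such datasets, each with a deterministically
derived child seed.

The default map has 18 loci: disease locus A at position 5, disease locus
B at position 13, the potentially associated marker at position 4 with
theta(4, A) = 0.  A free-recombination gap (theta = 0.5) between positions
9 and 10 makes A and B unlinked; all other adjacent recombination
fractions are 0.001.  Marker allele frequencies are 0.5 except for the
associated marker, whose allele-1 frequency defaults to the disease
allele frequency at A (matched frequencies give r^2 = D'^2).

Sibship sizes follow a truncated geometric distribution on 2..10; the
default ratio is a calibrated nuisance parameter of the generator (see
docs/methods.md), and the distribution is a plain table in the config, so
any published family-size distribution can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .haplotype_ld import HaplotypeFrequencies, build_haplotypes
from .pedigree import GeneticMap, Individual, Locus, Pedigree
from .trait_models import TwoLocusTraitModel, from_name, penetrance_from_counts

__all__ = [
    "SimulationConfig",
    "default_map",
    "truncated_geometric_sibship",
    "calibrate_sibship_ratio",
    "ascertained_mean_family_size",
    "DEFAULT_SIBSHIP_RATIO",
    "DEFAULT_SIBSHIP_DIST",
    "sample_sibship_size",
    "sample_family",
    "ascertain",
    "simulate_dataset",
    "simulate_study",
]

MIN_OFFSPRING = 2
MAX_OFFSPRING = 10

#: Geometric ratio for the default sibship-size distribution on 2..10.
#: Chosen (least squares) so that the family- and subject-retention
#: fractions after carrier pruning under the four epistatic models match
#: the study's full-scale sample-size reductions; ascertained DD sibships
#: then average ~3.6 offspring.  See docs/methods.md for the calibration.
DEFAULT_SIBSHIP_RATIO = 0.57


def truncated_geometric_sibship(
    ratio: float, lo: int = MIN_OFFSPRING, hi: int = MAX_OFFSPRING
) -> np.ndarray:
    """P(s offspring) proportional to ratio**(s - lo) on s = lo..hi."""
    w = ratio ** np.arange(0, hi - lo + 1, dtype=float)
    return w / w.sum()


def _child_disease_prob(mode: str, c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """P(child has the disease genotype) given parental disease-allele counts."""
    t1, t2 = c1 / 2.0, c2 / 2.0
    if mode == "dominant":
        return 1.0 - (1.0 - t1) * (1.0 - t2)
    return t1 * t2


def _family_affection_probs(trait: TwoLocusTraitModel):
    """Enumerate parental-genotype configurations.

    Returns (weights, p_child_affected) over the 81 combinations of
    parental disease-allele counts at the two loci; for the admixture
    heterogeneity rule, p is returned per causal locus instead.
    """
    counts = np.arange(3)
    hw = lambda q: np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    wa = hw(trait.freq_A)
    wb = hw(trait.freq_B)
    ca1, ca2, cb1, cb2 = np.meshgrid(counts, counts, counts, counts, indexing="ij")
    w = (wa[ca1] * wa[ca2] * wb[cb1] * wb[cb2]).ravel()
    ta = _child_disease_prob(trait.mode_A, ca1, ca2).ravel()
    tb = _child_disease_prob(trait.mode_B, cb1, cb2).ravel()
    f = trait.locus_penetrance
    if trait.architecture == "epistatic":
        return w, f * ta * tb
    if trait.het_rule == "admixture":
        return w, (f * ta, f * tb)
    return w, 1.0 - (1.0 - f * ta) * (1.0 - f * tb)


def ascertainment_probability(trait: TwoLocusTraitModel, sibship: int) -> float:
    """P(>= 1 affected offspring) for a random-mating family of given size."""
    w, p = _family_affection_probs(trait)
    if isinstance(p, tuple):
        miss = 0.5 * (1 - p[0]) ** sibship + 0.5 * (1 - p[1]) ** sibship
    else:
        miss = (1 - p) ** sibship
    return float((w * (1.0 - miss)).sum())


def ascertained_mean_sibship(ratio: float, trait: TwoLocusTraitModel) -> float:
    """Mean offspring per *ascertained* family for a geometric sibship ratio.

    Ascertainment favours larger sibships (more chances of an affected
    offspring), so this exceeds the raw mean; computed analytically by
    enumerating parental genotype configurations.
    """
    sizes = np.arange(MIN_OFFSPRING, MAX_OFFSPRING + 1)
    ps = truncated_geometric_sibship(ratio)
    a = np.array([ascertainment_probability(trait, int(s)) for s in sizes])
    w = ps * a
    return float((sizes * w).sum() / w.sum())


def calibrate_sibship_ratio(
    target_mean_sibship: float = 3.59,
    trait: TwoLocusTraitModel | None = None,
    tol: float = 1e-12,
) -> float:
    """Solve for the geometric ratio whose ascertained mean sibship matches
    the target (bisection; the mean is increasing in the ratio)."""
    trait = trait or from_name("DD")
    lo, hi = 1e-9, 0.999
    if not (
        ascertained_mean_sibship(lo, trait)
        <= target_mean_sibship
        <= ascertained_mean_sibship(hi, trait)
    ):
        raise ValueError("target mean sibship out of reachable range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ascertained_mean_sibship(mid, trait) < target_mean_sibship:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


DEFAULT_SIBSHIP_DIST = truncated_geometric_sibship(DEFAULT_SIBSHIP_RATIO)


def default_map(
    trait: TwoLocusTraitModel,
    d_prime: float = 1.0,
    marker_allele_freq: float | None = None,
    n_loci: int = 18,
) -> tuple[GeneticMap, HaplotypeFrequencies]:
    """The study map plus the founder haplotype table for the LD pair."""
    if n_loci != 18:
        raise ValueError("the default map has 18 loci")
    p1 = trait.freq_A if marker_allele_freq is None else marker_allele_freq
    haps = build_haplotypes(trait.freq_A, p1, d_prime)
    loci = []
    for i in range(n_loci):
        if i == 4:
            loci.append(Locus("disease", (trait.freq_A, 1 - trait.freq_A), "A"))
        elif i == 12:
            loci.append(Locus("disease", (trait.freq_B, 1 - trait.freq_B), "B"))
        elif i == 3:
            loci.append(Locus("marker", (p1, 1 - p1), "M4"))
        else:
            loci.append(Locus("marker", (0.5, 0.5), f"M{i + 1}"))
    theta = [0.001] * (n_loci - 1)
    theta[3] = 0.0  # associated marker rides with A
    theta[8] = 0.5  # free recombination: A and B unlinked
    gmap = GeneticMap(
        loci=tuple(loci), theta=tuple(theta), index_A=4, index_B=12,
        index_ld_marker=3,
    )
    assert gmap.compound_theta(gmap.index_A, gmap.index_B) == 0.5
    return gmap, haps


@dataclass
class SimulationConfig:
    """Everything needed to generate one experiment's family data."""

    gmap: GeneticMap
    trait: TwoLocusTraitModel
    haplotypes: HaplotypeFrequencies
    families_per_dataset: int = 50
    n_datasets: int = 500
    min_offspring: int = MIN_OFFSPRING
    max_offspring: int = MAX_OFFSPRING
    sibship_dist: np.ndarray = field(
        default_factory=lambda: DEFAULT_SIBSHIP_DIST.copy()
    )
    seed: int | None = None

    def __post_init__(self):
        if self.min_offspring < 2:
            raise ValueError("minimum sibship is 2 (four-member families)")
        if self.max_offspring > 10:
            raise ValueError("maximum sibship is 10")
        self.sibship_dist = np.asarray(self.sibship_dist, dtype=float)
        n = self.max_offspring - self.min_offspring + 1
        if self.sibship_dist.shape != (n,):
            raise ValueError(
                f"sibship distribution must have {n} entries "
                f"({self.min_offspring}..{self.max_offspring})"
            )
        if (self.sibship_dist < 0).any() or abs(self.sibship_dist.sum() - 1) > 1e-9:
            raise ValueError("sibship distribution must be a probability vector")

    @classmethod
    def from_model(
        cls,
        model: str | TwoLocusTraitModel,
        d_prime: float = 1.0,
        marker_allele_freq: float | None = None,
        **kwargs,
    ) -> "SimulationConfig":
        trait = from_name(model) if isinstance(model, str) else model
        gmap, haps = default_map(
            trait, d_prime=d_prime, marker_allele_freq=marker_allele_freq
        )
        return cls(gmap=gmap, trait=trait, haplotypes=haps, **kwargs)


def sample_sibship_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Draw an offspring count from the configured sibship distribution."""
    return int(
        rng.choice(
            np.arange(config.min_offspring, config.max_offspring + 1),
            p=config.sibship_dist,
        )
    )


# ---------------------------------------------------------------------------
# vectorised gene dropping
# ---------------------------------------------------------------------------

def _draw_founder_haplotypes(
    config: SimulationConfig, k: int, rng: np.random.Generator
) -> np.ndarray:
    """(k, 2 parents, 2 haplotypes, L) allele array (1/2 coding)."""
    gmap, haps = config.gmap, config.haplotypes
    L = gmap.n_loci
    freq1 = np.array([loc.allele_freqs[0] for loc in gmap.loci])
    founder = np.where(rng.random((k, 2, 2, L)) < freq1, 1, 2).astype(np.int8)
    # the LD marker is drawn conditionally on the disease allele at A
    p_given_dis, p_given_norm = config.haplotypes.conditional_marker1()
    at_a = founder[:, :, :, gmap.index_A]
    p1 = np.where(at_a == 1, p_given_dis, p_given_norm)
    founder[:, :, :, gmap.index_ld_marker] = np.where(
        rng.random((k, 2, 2)) < p1, 1, 2
    )
    return founder


def _drop_gametes(
    founder: np.ndarray, sibship: int, theta, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Transmit one recombinant gamete per parent to each of ``sibship``
    offspring.  Returns (genotypes (k, s, L, 2), bits (k, s, 2, L))."""
    k, _, _, L = founder.shape
    theta = np.asarray(theta, dtype=float)
    bits = np.empty((k, sibship, 2, L), dtype=np.int8)
    bits[..., 0] = rng.integers(0, 2, size=(k, sibship, 2))
    if L > 1:
        flips = rng.random((k, sibship, 2, L - 1)) < theta
        for l in range(1, L):
            bits[..., l] = bits[..., l - 1] ^ flips[..., l - 1]
    geno = np.empty((k, sibship, L, 2), dtype=np.int8)
    for p in (0, 1):  # 0 = father, 1 = mother
        haps = founder[:, p][:, None, :, :]  # (k, 1, 2, L)
        idx = bits[:, :, p, :][:, :, None, :]  # (k, s, 1, L)
        geno[..., p] = np.take_along_axis(haps, idx, axis=2)[:, :, 0, :]
    return geno, bits


def _assign_affection(
    config: SimulationConfig,
    founder: np.ndarray,
    offspring_geno: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Affection for parents (k, 2) and offspring (k, s)."""
    gmap, trait = config.gmap, config.trait
    par_ca = (founder[:, :, :, gmap.index_A] == 1).sum(axis=2)
    par_cb = (founder[:, :, :, gmap.index_B] == 1).sum(axis=2)
    off_ca = (offspring_geno[:, :, gmap.index_A, :] == 1).sum(axis=2)
    off_cb = (offspring_geno[:, :, gmap.index_B, :] == 1).sum(axis=2)
    if trait.architecture == "heterogeneity" and trait.het_rule == "admixture":
        # one causal locus per family
        causal_a = rng.integers(0, 2, size=founder.shape[0]).astype(bool)
        f = trait.locus_penetrance
        ind = lambda mode, c: (c >= 1) if mode == "dominant" else (c == 2)
        par_pen = np.where(
            causal_a[:, None],
            f * ind(trait.mode_A, par_ca),
            f * ind(trait.mode_B, par_cb),
        )
        off_pen = np.where(
            causal_a[:, None],
            f * ind(trait.mode_A, off_ca),
            f * ind(trait.mode_B, off_cb),
        )
    else:
        par_pen = penetrance_from_counts(trait, par_ca, par_cb)
        off_pen = penetrance_from_counts(trait, off_ca, off_cb)
    par_aff = rng.random(par_pen.shape) < par_pen
    off_aff = rng.random(off_pen.shape) < off_pen
    return par_aff, off_aff


def _simulate_size_batch(
    config: SimulationConfig, sibship: int, k: int, rng: np.random.Generator
):
    """Simulate k families of a fixed sibship size; return raw arrays."""
    founder = _draw_founder_haplotypes(config, k, rng)
    geno, _ = _drop_gametes(founder, sibship, config.gmap.theta, rng)
    par_aff, off_aff = _assign_affection(config, founder, geno, rng)
    return founder, geno, par_aff, off_aff


def _build_pedigree(
    family_id: int,
    founder: np.ndarray,
    offspring_geno: np.ndarray,
    par_aff: np.ndarray,
    off_aff: np.ndarray,
) -> Pedigree:
    members = [
        Individual(1, None, None, 1, bool(par_aff[0]),
                   founder[0].T.copy()),  # (L, 2): hap1, hap2
        Individual(2, None, None, 2, bool(par_aff[1]),
                   founder[1].T.copy()),
    ]
    for j in range(offspring_geno.shape[0]):
        members.append(
            Individual(
                3 + j, 1, 2, 1 + (j % 2), bool(off_aff[j]),
                offspring_geno[j].copy(),
            )
        )
    return Pedigree(family_id=family_id, members=members)


def sample_family(
    config: SimulationConfig, rng: np.random.Generator, family_id: int = 1
) -> Pedigree:
    """Simulate one (not-yet-ascertained) nuclear family."""
    s = sample_sibship_size(config, rng)
    founder, geno, par_aff, off_aff = _simulate_size_batch(config, s, 1, rng)
    return _build_pedigree(family_id, founder[0], geno[0], par_aff[0], off_aff[0])


def ascertain(ped: Pedigree) -> bool:
    """True iff >= 1 affected offspring and >= 4 members."""
    return ped.n_members >= 4 and any(o.affected for o in ped.offspring)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    first_family_id: int = 1,
) -> list[Pedigree]:
    """Rejection-sample ascertained families until the dataset is full.

    Families are simulated in vectorised batches grouped by sibship size;
    a family is kept iff it has at least one affected offspring (the
    four-member minimum is automatic for sibships >= 2).
    """
    need = config.families_per_dataset
    accepted: list[tuple] = []
    # initial batch sized from the analytic ascertainment probability
    sizes_all = np.arange(config.min_offspring, config.max_offspring + 1)
    p_asc = float(
        sum(
            config.sibship_dist[i]
            * ascertainment_probability(config.trait, int(s))
            for i, s in enumerate(sizes_all)
        )
    )
    batch = max(64, int(1.3 * need / max(p_asc, 1e-6)))
    while len(accepted) < need:
        sizes = rng.choice(sizes_all, size=batch, p=config.sibship_dist)
        # simulate grouped by sibship size, but keep families in the order
        # their sizes were drawn: truncating the surplus must not favour
        # any particular family size
        slots: list = [None] * batch
        for s in sizes_all:
            pos = np.nonzero(sizes == s)[0]
            if pos.size == 0:
                continue
            founder, geno, par_aff, off_aff = _simulate_size_batch(
                config, int(s), int(pos.size), rng
            )
            keep = off_aff.any(axis=1)
            for j, i in enumerate(pos):
                if keep[j]:
                    slots[i] = (founder[j], geno[j], par_aff[j], off_aff[j])
        accepted.extend(fam for fam in slots if fam is not None)
        batch = max(64, int(0.4 * need / max(p_asc, 1e-6)))
    return [
        _build_pedigree(first_family_id + i, *accepted[i]) for i in range(need)
    ]


def simulate_study(config: SimulationConfig, seed: int | None = None):
    """Yield (dataset_index, child_seed, pedigrees) for each dataset.

    Per-dataset seeds are derived deterministically from the master seed
    via numpy's SeedSequence spawning, so datasets are reproducible
    independently of one another.
    """
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    children = master.spawn(config.n_datasets)
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.Generator(np.random.PCG64(child))
        yield i, child_seed, simulate_dataset(config, rng)
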