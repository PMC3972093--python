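import numpy as np
import pytest

from linkstrat.pedigree import GeneticMap, Individual, Locus, Pedigree
from linkstrat.linkage_engine import AnalysisModel
from linkstrat.simulator import SimulationConfig

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def small_map():
    """Four-locus map: marker, disease A, disease B, marker."""
    loci = (
        Locus("marker", (0.5, 0.5), "M1"),
        Locus("disease", (0.2, 0.8), "A"),
        Locus("disease", (0.2, 0.8), "B"),
        Locus("marker", (0.5, 0.5), "M2"),
    )
    return GeneticMap(loci, (0.1, 0.05, 0.1), index_A=1, index_B=2,
                      index_ld_marker=0)


def make_individual(ind_id, father, mother, sex, affected, genotypes):
    return Individual(
        id=ind_id,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affected=affected,
        genotypes=np.asarray(genotypes, dtype=np.int8),
    )


def random_nuclear_family(rng, gmap, n_offspring, affected_rate=0.5,
                          missing_rate=0.2, family_id=1,
                          duplicate_rate=0.0):
    """Random Mendelian-consistent nuclear family on an arbitrary map."""
    L = gmap.n_loci
    fg = rng.integers(1, 3, (L, 2)).astype(np.int8)
    mg = rng.integers(1, 3, (L, 2)).astype(np.int8)
    members = [
        make_individual(1, None, None, 1, bool(rng.random() < affected_rate), fg),
        make_individual(2, None, None, 2, bool(rng.random() < affected_rate), mg),
    ]
    genos = []
    for j in range(n_offspring):
        if genos and rng.random() < duplicate_rate:
            g = genos[int(rng.integers(0, len(genos)))].copy()
        else:
            bits = rng.integers(0, 2, (2, L))
            g = np.stack(
                [fg[np.arange(L), bits[0]], mg[np.arange(L), bits[1]]], axis=1
            ).astype(np.int8)
            if rng.random() < missing_rate:
                g[int(rng.integers(0, L))] = 0
        genos.append(g)
        members.append(
            make_individual(3 + j, 1, 2, 1 + (j % 2),
                            bool(rng.random() < affected_rate), g)
        )
    return Pedigree(family_id=family_id, members=members)


def random_small_analysis(rng):
    return AnalysisModel(
        mode=("dominant", "recessive")[int(rng.integers(0, 2))],
        disease_allele_freq=float(rng.uniform(0.05, 0.3)),
        penetrance_carrier=float(rng.uniform(0.3, 1.0)),
    )


def random_small_map(rng, n_markers):
    """Random map with n_markers markers and disease loci A and B inserted
    so that B has flanking markers (oracle-sized)."""
    loci = [
        Locus("marker", (float(f), float(1 - f)), f"M{i + 1}")
        for i, f in enumerate(rng.uniform(0.2, 0.8, n_markers))
    ]
    if n_markers == 2:
        full = [loci[0], Locus("disease", (0.15, 0.85), "A"),
                Locus("disease", (0.2, 0.8), "B"), loci[1]]
    else:
        full = (
            [loci[0], Locus("disease", (0.15, 0.85), "A")]
            + loci[1:-1]
            + [Locus("disease", (0.2, 0.8), "B"), loci[-1]]
        )
    theta = tuple(float(t) for t in rng.uniform(0.0, 0.4, len(full) - 1))
    return GeneticMap(tuple(full), theta, index_A=1, index_B=len(full) - 2,
                      index_ld_marker=0)


@pytest.fixture
def dd_config():
    """Small DD-model simulation config for quick end-to-end tests."""
    return SimulationConfig.from_model("DD", families_per_dataset=10,
                                       n_datasets=2)


def illustrative_family(gmap):
    """Synthetic eight-member family illustrating DD pruning.

    Built to mirror the canonical worked example: an affected mother
    (id 2) and two affected children (ids 4 and 6); offspring 5, 7 and 8
    do not carry the disease allele at locus A and are removed by
    dominant-at-A pruning, while unaffected carrier offspring 3 is kept.
    Genotypes at A and B are Mendelian-consistent with an aa x Aa and
    Bb x Bb parental pair; marker genotypes are arbitrary heterozygotes.
    """
    L = gmap.n_loci
    iA, iB = gmap.index_A, gmap.index_B

    def geno(a_pair, b_pair):
        g = np.ones((L, 2), dtype=np.int8)
        g[:, 1] = 2
        g[iA] = a_pair
        g[iB] = b_pair
        return g

    # allele 1 = disease allele; father aa Bb, mother Aa Bb (affected needs
    # the epistatic partner: mother carries both)
    father = make_individual(1, None, None, 1, False, geno((2, 2), (1, 2)))
    mother = make_individual(2, None, None, 2, True, geno((1, 2), (1, 2)))
    # offspring genotypes are ordered (paternal, maternal): the disease
    # allele at A can only arrive maternally
    rows = [
        (3, False, (2, 1), (2, 2)),  # carrier at A, no B genotype: kept
        (4, True, (2, 1), (1, 1)),  # affected: kept
        (5, False, (2, 2), (1, 2)),  # non-carrier at A: pruned
        (6, True, (2, 1), (1, 2)),  # affected: kept
        (7, False, (2, 2), (2, 2)),  # pruned
        (8, False, (2, 2), (1, 2)),  # pruned
    ]
    members = [father, mother] + [
        make_individual(i, 1, 2, 1 + (i % 2), aff, geno(a, b))
        for i, aff, a, b in rows
    ]
    return Pedigree(family_id=1, members=members)
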