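"""Pedigrees, genotypes, the genetic map, and LINKAGE-format interchange.

The in-memory model is deliberately simple: two-generation nuclear families
(two founders, 2-10 offspring) with biallelic loci.  Genotypes are stored
*ordered* -- column 0 is the paternally derived allele, column 1 the
maternally derived allele -- because the simulator knows the true phase.
Phase is erased on LINKAGE export, which is what downstream linkage
software actually observes.

Allele coding: alleles are the integers 1 and 2; 0 means missing.  At a
disease locus, allele 1 is the disease allele.  Affection status follows
the LINKAGE convention on disk (2 = affected, 1 = unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = 0

__all__ = [
    "MISSING",
    "Locus",
    "GeneticMap",
    "Individual",
    "Pedigree",
    "LinkageFormatError",
    "PedigreeError",
    "compose_theta",
    "haldane_cm",
    "inverse_haldane",
    "mendelian_consistent",
    "write_linkage",
    "read_linkage",
    "write_truth",
]


class PedigreeError(ValueError):
    """A pedigree violates a structural invariant."""


class LinkageFormatError(ValueError):
    """A LINKAGE-format file could not be parsed.

    Carries ``line`` (1-based line number) when the error is positional.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def compose_theta(t1: float, t2: float) -> float:
    """Recombination fraction across two adjacent intervals (no interference).

    An odd number of crossovers overall requires an odd count in exactly one
    of the intervals: t1(1-t2) + t2(1-t1).  Composing with 0.5 yields 0.5,
    so a single free-recombination gap unlinks everything across it.
    """
    return t1 * (1.0 - t2) + t2 * (1.0 - t1)


def haldane_cm(theta: float) -> float:
    """Map distance in Morgans under Haldane's function, d = -ln(1-2*theta)/2.

    theta is clipped just below 0.5 so that unlinked gaps stay finite for
    plotting/coordinate purposes (documented display convention).
    """
    t = min(float(theta), 0.499999)
    return -0.5 * np.log(1.0 - 2.0 * t)


def inverse_haldane(d: float) -> float:
    """Recombination fraction for a map distance d Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * float(d)))


@dataclass(frozen=True)
class Locus:
    """A biallelic locus: a SNP marker or an (unobserved) disease locus."""

    kind: str  # "marker" | "disease"
    allele_freqs: tuple[float, float]
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("marker", "disease"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if len(self.allele_freqs) != 2:
            raise ValueError("loci are biallelic: exactly two allele frequencies")
        if abs(sum(self.allele_freqs) - 1.0) > 1e-12:
            raise ValueError(
                f"allele frequencies must sum to 1, got {self.allele_freqs}"
            )
        if any(f < 0 for f in self.allele_freqs):
            raise ValueError("allele frequencies must be non-negative")


@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci with recombination fractions between adjacent pairs.

    ``index_A`` / ``index_B`` locate the two disease loci (0-based);
    ``index_ld_marker`` locates the marker that may be in linkage
    disequilibrium with the disease allele at A.
    """

    loci: tuple[Locus, ...]
    theta: tuple[float, ...]
    index_A: int
    index_B: int
    index_ld_marker: int

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))
        if len(self.theta) != len(self.loci) - 1:
            raise ValueError("need exactly one theta per adjacent locus pair")
        if any(t < 0 or t > 0.5 for t in self.theta):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if self.index_A == self.index_B:
            raise ValueError("disease loci A and B must be distinct")
        for idx, kind in [(self.index_A, "disease"), (self.index_B, "disease"),
                          (self.index_ld_marker, "marker")]:
            if not 0 <= idx < len(self.loci):
                raise ValueError(f"locus index {idx} out of range")
            if self.loci[idx].kind != kind:
                raise ValueError(f"locus {idx} should be a {kind} locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def marker_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.loci) if l.kind == "marker"]

    def compound_theta(self, i: int, j: int) -> float:
        """Recombination fraction between loci i and j (i < j), composed
        across intervening intervals assuming no interference."""
        if i > j:
            i, j = j, i
        t = 0.0
        for k in range(i, j):
            t = compose_theta(t, self.theta[k])
        return t

    def positions(self) -> np.ndarray:
        """Cumulative Haldane map positions (Morgans) of every locus."""
        d = np.concatenate([[0.0], np.cumsum([haldane_cm(t) for t in self.theta])])
        return d


@dataclass
class Individual:
    """A pedigree member.  Founders have no parent ids.

    ``genotypes`` is an (n_loci, 2) int8 array; for offspring column 0 is
    the paternal allele.  Sex is non-informative for the autosomal models
    handled here and is carried only for file interchange.
    """

    id: int
    father_id: int | None
    mother_id: int | None
    sex: int
    affected: bool
    genotypes: np.ndarray

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def role(self) -> str:
        return "founder" if self.is_founder else "offspring"


@dataclass
class Pedigree:
    """A two-generation nuclear family."""

    family_id: int
    members: list[Individual] = field(default_factory=list)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def offspring(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def father(self) -> Individual:
        return next(m for m in self.founders if m.sex == 1)

    @property
    def mother(self) -> Individual:
        return next(m for m in self.founders if m.sex == 2)

    def member(self, ind_id: int) -> Individual:
        for m in self.members:
            if m.id == ind_id:
                return m
        raise KeyError(f"no individual {ind_id} in family {self.family_id}")

    def validate_nuclear(self) -> None:
        founders = self.founders
        if len(founders) != 2:
            raise PedigreeError(
                f"family {self.family_id}: expected 2 founders, got {len(founders)}"
            )
        if {f.sex for f in founders} != {1, 2}:
            raise PedigreeError(f"family {self.family_id}: founders must be a couple")
        parent_ids = {f.id for f in founders}
        for o in self.offspring:
            if o.father_id not in parent_ids or o.mother_id not in parent_ids:
                raise PedigreeError(
                    f"family {self.family_id}, individual {o.id}: "
                    "parent not present in pedigree"
                )


def mendelian_consistent(ped: Pedigree, ordered: bool = True) -> bool:
    """Check every offspring genotype against the parents at every locus.

    With ``ordered=True`` the paternal/maternal columns are trusted: each
    offspring allele must equal one of the corresponding parent's two
    alleles.  With ``ordered=False`` only unordered compatibility is
    required (some assignment of offspring alleles to parents works).
    Missing alleles (0) are treated as compatible with anything.
    """
    father, mother = ped.father, ped.mother
    fg, mg = father.genotypes, mother.genotypes
    for o in ped.offspring:
        og = o.genotypes
        for l in range(og.shape[0]):
            a, b = int(og[l, 0]), int(og[l, 1])
            fa = {int(fg[l, 0]), int(fg[l, 1])} | {MISSING}
            ma = {int(mg[l, 0]), int(mg[l, 1])} | {MISSING}
            if MISSING in (int(fg[l, 0]), int(fg[l, 1])):
                fa |= {1, 2}
            if MISSING in (int(mg[l, 0]), int(mg[l, 1])):
                ma |= {1, 2}
            if ordered:
                if not ((a in fa or a == MISSING) and (b in ma or b == MISSING)):
                    return False
            else:
                ok = ((a in fa or a == MISSING) and (b in ma or b == MISSING)) or (
                    (b in fa or b == MISSING) and (a in ma or a == MISSING)
                )
                if not ok:
                    return False
    return True


# ---------------------------------------------------------------------------
# LINKAGE-format I/O (pre-makeped dialect)
# ---------------------------------------------------------------------------

def _exported_indices(gmap: GeneticMap, include_disease: bool) -> list[int]:
    if include_disease:
        return list(range(gmap.n_loci))
    return gmap.marker_indices


def write_linkage(
    pedigrees: list[Pedigree],
    gmap: GeneticMap,
    path_ped,
    path_loc,
    include_disease: bool = False,
    truth_path=None,
) -> None:
    """Write a pre-makeped LINKAGE pedigree file and a locus file.

    Each pedigree line is: family, individual, father, mother, sex,
    affection (2 affected / 1 unaffected), then one allele pair per
    exported locus (0 = missing).  By default the two disease loci are
    *not* exported -- analysis software must only ever see marker
    genotypes plus affection; the true disease-locus genotypes can be
    written to a tab-separated ``truth_path`` sidecar instead.
    """
    idx = _exported_indices(gmap, include_disease)
    n_expected = gmap.n_loci
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            if m.genotypes.shape[0] != n_expected:
                raise PedigreeError(
                    f"family {ped.family_id}, individual {m.id}: "
                    f"{m.genotypes.shape[0]} loci, map has {n_expected}"
                )
            cols = [
                str(ped.family_id),
                str(m.id),
                str(m.father_id or 0),
                str(m.mother_id or 0),
                str(m.sex),
                "2" if m.affected else "1",
            ]
            for l in idx:
                cols.append(str(int(m.genotypes[l, 0])))
                cols.append(str(int(m.genotypes[l, 1])))
            lines.append(" ".join(cols))
    with open(path_ped, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))

    with open(path_loc, "w") as fh:
        fh.write(f"{len(idx)}\n")
        for l in idx:
            loc = gmap.loci[l]
            fh.write(
                f"{loc.label or f'locus{l + 1}'}\t{loc.kind}\t"
                f"{loc.allele_freqs[0]:.10g}\t{loc.allele_freqs[1]:.10g}\n"
            )
        thetas = [
            f"{gmap.compound_theta(idx[k], idx[k + 1]):.10g}"
            for k in range(len(idx) - 1)
        ]
        fh.write(" ".join(thetas) + "\n")

    if truth_path is not None:
        write_truth(pedigrees, gmap, truth_path)


def write_truth(pedigrees: list[Pedigree], gmap: GeneticMap, path) -> None:
    """Tab-separated truth sidecar: family, individual, genotype at A, at B."""
    with open(path, "w") as fh:
        fh.write("family\tindividual\tgeno_A\tgeno_B\n")
        for ped in pedigrees:
            for m in ped.members:
                ga = m.genotypes[gmap.index_A]
                gb = m.genotypes[gmap.index_B]
                fh.write(
                    f"{ped.family_id}\t{m.id}\t"
                    f"{int(ga[0])}/{int(ga[1])}\t{int(gb[0])}/{int(gb[1])}\n"
                )


def read_truth(path) -> dict[tuple[int, int], tuple[tuple[int, int], tuple[int, int]]]:
    """Read a truth sidecar into {(family, individual): (genoA, genoB)}."""
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family"):
            raise LinkageFormatError("missing truth header", line=1)
        for ln, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            try:
                fam, ind, ga, gb = raw.split()
                a = tuple(int(x) for x in ga.split("/"))
                b = tuple(int(x) for x in gb.split("/"))
            except ValueError as exc:
                raise LinkageFormatError(str(exc), line=ln) from None
            out[(int(fam), int(ind))] = (a, b)
    return out


def read_linkage(path_ped, path_loc) -> tuple[list[Pedigree], list[Locus], list[float]]:
    """Read the dialect produced by :func:`write_linkage`.

    Returns (pedigrees, loci, thetas).  Phase is unknown on disk, so each
    genotype is stored order-normalised (smaller allele first); the
    round-trip with write_linkage is the identity up to phase.
    """
    loci: list[Locus] = []
    with open(path_loc) as fh:
        try:
            n = int(fh.readline().split()[0])
        except (ValueError, IndexError):
            raise LinkageFormatError("bad locus count", line=1) from None
        for k in range(n):
            ln = k + 2
            parts = fh.readline().split()
            if len(parts) != 4:
                raise LinkageFormatError("expected: label kind f1 f2", line=ln)
            label, kind, f1, f2 = parts
            loci.append(Locus(kind=kind, allele_freqs=(float(f1), float(f2)),
                              label=label))
        theta_line = fh.readline().split()
        if n > 1 and len(theta_line) != n - 1:
            raise LinkageFormatError(
                f"expected {n - 1} recombination fractions", line=n + 2
            )
        thetas = [float(t) for t in theta_line]

    rows: dict[int, list[tuple[int, Individual]]] = {}
    order: list[int] = []
    with open(path_ped) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6 + 2 * n:
                raise LinkageFormatError(
                    f"expected {6 + 2 * n} columns, got {len(parts)}", line=ln
                )
            try:
                fam, ind, fa, mo, sex, aff = (int(x) for x in parts[:6])
                alleles = np.array([int(x) for x in parts[6:]], dtype=np.int8)
            except ValueError:
                raise LinkageFormatError("non-integer field", line=ln) from None
            g = alleles.reshape(n, 2)
            g = np.sort(g, axis=1)  # phase unknown: normalise order
            # missing (0) sorts first; keep (0, x) form
            member = Individual(
                id=ind,
                father_id=fa or None,
                mother_id=mo or None,
                sex=sex,
                affected=(aff == 2),
                genotypes=g,
            )
            if fam not in rows:
                rows[fam] = []
                order.append(fam)
            rows[fam].append((ln, member))

    pedigrees = []
    for fam in order:
        members = [m for _, m in rows[fam]]
        ids = {m.id for m in members}
        for ln, m in rows[fam]:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise LinkageFormatError(
                        f"family {fam}, individual {m.id}: unknown parent {pid}",
                        line=ln,
                    )
        pedigrees.append(Pedigree(family_id=fam, members=members))
    return pedigrees, loci, thetas
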