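"""Amplicon haplotype phasing and blood-group allele matching.

Long single-molecule amplicon reads phase heterozygous variants directly:
each read reports the allele it carries at every heterozygous site inside its
fragment.  Reads of one fragment are clustered into the two haplotypes by
greedy 2-clustering seeded from the best-covered site and refined by majority
vote; consecutive overlapping fragments (the study design tiles the gene in
three amplicons overlapping by >1 kb) are stitched by matching alleles at the
heterozygous sites shared across the overlap.  The resulting variant sets are
matched against named allele definitions (e.g. ABO*O.01.02) by exact set
equality, falling back to the nearest allele by symmetric difference with a
"novel, X-like" label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

REF, ALT = "ref", "alt"


@dataclass
class AmpliconRead:
    """Per-read allele observations at the heterozygous sites of one fragment."""

    fragment_id: int
    observations: dict[str, str]  # site id → "ref" | "alt"

    def __post_init__(self) -> None:
        for site, allele in self.observations.items():
            if allele not in (REF, ALT):
                raise ValueError(f"observation at {site} must be ref/alt, got {allele!r}")


@dataclass
class PhasedFragment:
    """Two per-fragment haplotype consensus calls with read support."""

    fragment_id: int
    consensus: tuple[dict[str, str], dict[str, str]]
    support: tuple[dict[str, int], dict[str, int]]
    ambiguous_sites: list[str] = field(default_factory=list)
    unsupported: tuple[bool, bool] = (False, False)
    read_assignments: list[int] = field(default_factory=list)


@dataclass
class Haplotype:
    """A full-gene phased variant set."""

    variants: set[str]
    support: dict[str, int] = field(default_factory=dict)
    label: str = ""


@dataclass(frozen=True)
class AlleleDefinition:
    name: str
    variants: frozenset[str]


@dataclass
class AlleleMatch:
    """Result of matching one haplotype against the allele table."""

    exact: bool
    names: list[str]  # the exact allele, or the nearest allele(s) on a tie
    extra: set[str] = field(default_factory=set)
    missing: set[str] = field(default_factory=set)
    distance: int = 0

    @property
    def label(self) -> str:
        joined = "/".join(self.names)
        if self.exact:
            return joined
        parts = []
        if self.extra:
            parts.append("extra: " + "; ".join(sorted(self.extra)))
        if self.missing:
            parts.append("missing: " + "; ".join(sorted(self.missing)))
        detail = f" ({', '.join(parts)})" if parts else ""
        return f"novel, {joined}-like{detail}"


class PhasingError(ValueError):
    pass


def _agreement(obs: dict[str, str], consensus: dict[str, str]) -> tuple[int, int]:
    """(matches, comparisons) between a read and a cluster consensus."""
    match = comp = 0
    for site, allele in obs.items():
        call = consensus.get(site)
        if call is None:
            continue
        comp += 1
        match += call == allele
    return match, comp


def _consensus(reads: list[AmpliconRead]) -> tuple[dict, dict, list[str]]:
    """Majority-vote consensus over a read cluster; ties flagged ambiguous."""
    votes: dict[str, dict[str, int]] = {}
    for r in reads:
        for site, allele in r.observations.items():
            votes.setdefault(site, {REF: 0, ALT: 0})[allele] += 1
    consensus: dict[str, str] = {}
    support: dict[str, int] = {}
    ambiguous: list[str] = []
    for site, v in votes.items():
        support[site] = v[REF] + v[ALT]
        if v[REF] == v[ALT]:
            ambiguous.append(site)
        else:
            consensus[site] = REF if v[REF] > v[ALT] else ALT
    return consensus, support, ambiguous


def phase_fragment(reads: list[AmpliconRead], n_iter: int = 3) -> PhasedFragment:
    """Cluster one fragment's reads into its two haplotypes.

    Seeds the two clusters from the best-covered site showing both alleles,
    then alternates consensus building and majority-agreement reassignment.
    Raises :class:`PhasingError` when several reads are identical at every
    site (no phase signal); a single read yields one supported haplotype and
    one empty, flagged-unsupported haplotype.
    """
    if not reads:
        raise PhasingError("no reads supplied")
    frag = reads[0].fragment_id
    sites = sorted({s for r in reads for s in r.observations})
    if not sites:
        raise PhasingError(f"fragment {frag}: reads carry no site observations")

    if len(reads) == 1:
        cons, supp, _ = _consensus(reads)
        return PhasedFragment(
            fragment_id=frag,
            consensus=(cons, {}),
            support=(supp, {}),
            unsupported=(False, True),
            read_assignments=[0],
        )

    # seed: the most-covered site at which both alleles are seen
    def coverage(site):
        obs = [r.observations.get(site) for r in reads]
        n_ref = obs.count(REF)
        n_alt = obs.count(ALT)
        return (min(n_ref, n_alt) > 0, n_ref + n_alt)

    seed = max(sites, key=coverage)
    if coverage(seed)[0] is False:
        raise PhasingError(
            f"fragment {frag} uninformative: reads are identical at every "
            "heterozygous site"
        )

    assign = []
    for r in reads:
        allele = r.observations.get(seed)
        assign.append(0 if allele == REF else 1 if allele == ALT else -1)

    for _ in range(n_iter):
        clusters = (
            [r for r, a in zip(reads, assign) if a == 0],
            [r for r, a in zip(reads, assign) if a == 1],
        )
        cons = tuple(_consensus(c)[0] if c else {} for c in clusters)
        new_assign = []
        for r, prev in zip(reads, assign):
            m0, c0 = _agreement(r.observations, cons[0])
            m1, c1 = _agreement(r.observations, cons[1])
            s0 = m0 - (c0 - m0)
            s1 = m1 - (c1 - m1)
            if s0 > s1:
                new_assign.append(0)
            elif s1 > s0:
                new_assign.append(1)
            else:
                new_assign.append(prev if prev != -1 else 0)
        if new_assign == assign:
            assign = new_assign
            break
        assign = new_assign

    clusters = (
        [r for r, a in zip(reads, assign) if a == 0],
        [r for r, a in zip(reads, assign) if a == 1],
    )
    built = [_consensus(c) if c else ({}, {}, []) for c in clusters]
    return PhasedFragment(
        fragment_id=frag,
        consensus=(built[0][0], built[1][0]),
        support=(built[0][1], built[1][1]),
        ambiguous_sites=sorted(set(built[0][2]) | set(built[1][2])),
        unsupported=(not clusters[0], not clusters[1]),
        read_assignments=assign,
    )


def stitch_haplotypes(per_fragment: list[PhasedFragment]) -> tuple[Haplotype, Haplotype]:
    """Join per-fragment phases into two full-gene haplotypes.

    Consecutive fragments must share at least one heterozygous site with a
    consensus call on both sides; the orientation maximising allele agreement
    across shared sites is chosen, and a tie (no net phase signal in the
    overlap) is an error naming the junction.  Disagreeing shared sites under
    the chosen orientation are resolved by total read support.
    """
    if not per_fragment:
        raise PhasingError("no phased fragments supplied")
    oriented: list[tuple[dict, dict, dict, dict]] = []
    first = per_fragment[0]
    oriented.append((*first.consensus, *first.support))
    for prev, cur in zip(per_fragment, per_fragment[1:]):
        prev_a = oriented[-1][0]
        prev_b = oriented[-1][1]
        ca, cb = cur.consensus
        shared = (set(prev_a) | set(prev_b)) & (set(ca) | set(cb))
        if not shared:
            raise PhasingError(
                f"phase cannot be joined between fragments {prev.fragment_id} "
                f"and {cur.fragment_id}: no shared heterozygous site with a "
                "consensus call in the overlap"
            )
        same = flipped = 0
        for site in shared:
            for p_cons, c_same, c_flip in ((prev_a, ca, cb), (prev_b, cb, ca)):
                p = p_cons.get(site)
                if p is None:
                    continue
                if c_same.get(site) == p:
                    same += 1
                if c_flip.get(site) == p:
                    flipped += 1
        if same == flipped:
            raise PhasingError(
                f"conflicting join between fragments {prev.fragment_id} and "
                f"{cur.fragment_id}: shared sites {sorted(shared)} give no net "
                "orientation"
            )
        if same > flipped:
            oriented.append((ca, cb, *cur.support))
        else:
            oriented.append((cb, ca, cur.support[1], cur.support[0]))

    haps = []
    for k in range(2):
        merged: dict[str, str] = {}
        support: dict[str, int] = {}
        for entry in oriented:
            cons, supp = entry[k], entry[2 + k]
            for site, allele in cons.items():
                s = supp.get(site, 0)
                # overlap sites seen twice: the higher-support call wins
                if site not in merged or s > support[site]:
                    merged[site] = allele
                    support[site] = s
        haps.append(
            Haplotype(
                variants={site for site, a in merged.items() if a == ALT},
                support=support,
            )
        )
    return haps[0], haps[1]


def attach_homozygous(haps: tuple[Haplotype, Haplotype], hom_variants: set[str]) -> None:
    """Homozygous variants carry no phase signal; add them to both haplotypes."""
    for h in haps:
        h.variants |= set(hom_variants)


# ---------------------------------------------------------------------------
# Allele matching
# ---------------------------------------------------------------------------

def _norm(v: str) -> str:
    return v.replace(" ", "")


#: the allele definitions used in the study (not the full ISBT table):
#: ABO*O.01.02 as observed, and ABO*A2.01 defined by its two coding changes.
DEFAULT_ALLELES = [
    AlleleDefinition(
        "ABO*O.01.02",
        frozenset(
            {
                "c.106G>T", "c.188G>A", "c.189C>T", "c.220C>T", "c.261delG",
                "c.297A>G", "c.646T>A", "c.681G>A", "c.771C>T", "c.829G>A",
            }
        ),
    ),
    AlleleDefinition("ABO*A2.01", frozenset({"c.467C>T", "c.1061delC"})),
]


def match_allele(hap, table: list[AlleleDefinition]) -> AlleleMatch:
    """Match a haplotype's variant set against named allele definitions.

    Exact set equality wins; otherwise the nearest allele(s) by symmetric
    difference are reported with the extra/missing variants, as a
    "novel, X-like" call.  Ties report every tied allele name.
    """
    if not table:
        raise ValueError("allele table is empty")
    variants = {_norm(v) for v in (hap.variants if isinstance(hap, Haplotype) else hap)}
    best: list[AlleleDefinition] = []
    best_d: int | None = None
    for allele in table:
        defn = {_norm(v) for v in allele.variants}
        if defn == variants:
            return AlleleMatch(exact=True, names=[allele.name], distance=0)
        d = len(defn ^ variants)
        if best_d is None or d < best_d:
            best, best_d = [allele], d
        elif d == best_d:
            best.append(allele)
    # extra/missing reported against the first nearest allele for determinism
    ref_set = {_norm(v) for v in best[0].variants}
    extra = variants - ref_set
    missing = ref_set - variants
    return AlleleMatch(
        exact=False,
        names=[a.name for a in best],
        extra=extra,
        missing=missing,
        distance=best_d or 0,
    )


def load_allele_table(path: str | Path) -> list[AlleleDefinition]:
    """Read a `name<TAB>semicolon-joined HGVS c. list` allele table."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, _, variants = line.partition("\t")
        if not variants:
            raise ValueError(f"malformed allele table line: {raw!r}")
        out.append(
            AlleleDefinition(
                name.strip(),
                frozenset(_norm(v) for v in variants.split(";") if v.strip()),
            )
        )
    if not out:
        raise ValueError(f"{path}: no allele definitions found")
    return out


def write_allele_table(table: list[AlleleDefinition], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#name\tvariants\n")
        for allele in table:
            fh.write(f"{allele.name}\t{';'.join(sorted(allele.variants))}\n")
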