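"""Synthetic-data generators with known ground truth for every pipeline stage.

Everything downstream of this module can be exercised without downloads: a
donor-window catalog drawn from a known PWM, a surrogate two-exon gene whose
damaged donor, planted cryptic site and protein consequence are all known by
construction, a seven-exon diploid gene carrying the study's two haplotype
variant sets, amplicon reads from three >1 kb-overlapping fragments, and a
minigene construct with vector-anchored primers.

All generators draw from named substreams of one seed, so identical
(config, seed) pairs give byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import (
    BASES,
    DonorPWM,
    SpliceCatalog,
    catalog_from_counts,
)
from .minigene import MinigeneConstruct, truncate_intron
from .transcript import CVariant, GeneModel

#: stylised human 5' donor-site base frequencies (exon −3..−1, intron +1..+6);
#: +1/+2 are invariant GT.  Values are rounded literature-style consensus
#: weights, not a rebuild of any specific genome-wide catalog.
DEFAULT_DONOR_PWM = np.array(
    [
        #  A     C     G     T
        [0.33, 0.37, 0.18, 0.12],  # -3
        [0.60, 0.13, 0.14, 0.13],  # -2
        [0.09, 0.04, 0.79, 0.08],  # -1
        [0.00, 0.00, 1.00, 0.00],  # +1
        [0.00, 0.00, 0.00, 1.00],  # +2
        [0.60, 0.03, 0.33, 0.04],  # +3
        [0.70, 0.08, 0.10, 0.12],  # +4
        [0.08, 0.06, 0.78, 0.08],  # +5
        [0.16, 0.16, 0.20, 0.48],  # +6
    ]
)

#: the two haplotype variant sets observed in the study (Ael proband):
#: a common O allele and the novel A2-background allele with the intron-1
#: donor variant.
HAPLOTYPE_O0102 = (
    "c.106G>T", "c.188G>A", "c.189C>T", "c.220C>T", "c.261delG",
    "c.297A>G", "c.646T>A", "c.681G>A", "c.771C>T", "c.829G>A",
)
HAPLOTYPE_AEL_NEW = ("c.28+5G>A", "c.467C>T", "c.1061delC")

_STREAMS = {
    "catalog": 1,
    "gene": 2,
    "reads": 3,
    "fixture": 4,
    "construct": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study conditions
    (three amplicons overlapping >1 kb; the two observed haplotypes) with
    amplicon depth and error picked as realistic HiFi-consensus figures.
    """

    seed: int = 0
    n_donor_sites: int = 5000
    pwm_spec: np.ndarray | None = None
    n_fragments: int = 3
    overlap_bp: int = 1200
    reads_per_fragment: int = 20
    per_site_error: float = 0.02
    planted_haplotypes: tuple[tuple[str, ...], tuple[str, ...]] = (
        HAPLOTYPE_O0102,
        HAPLOTYPE_AEL_NEW,
    )

    def resolved_pwm(self) -> np.ndarray:
        spec = DEFAULT_DONOR_PWM if self.pwm_spec is None else np.asarray(self.pwm_spec)
        if spec.shape != (9, 4):
            raise ValueError(f"pwm_spec must be 9x4, got {spec.shape}")
        if not np.allclose(spec.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm_spec position frequencies must sum to 1")
        return spec


# ---------------------------------------------------------------------------
# Catalog simulation
# ---------------------------------------------------------------------------

def simulate_catalog(config: SimulationConfig) -> tuple[SpliceCatalog, DonorPWM]:
    """Draw donor 9-mers independently per position from the PWM spec.

    GT is forced at +1/+2 regardless of the spec, matching the definition of
    the catalog.  Returns the catalog and the true generating PWM.
    """
    if config.n_donor_sites < 1:
        raise ValueError("n_donor_sites must be ≥ 1")
    spec = config.resolved_pwm().copy()
    spec[3] = [0.0, 0.0, 1.0, 0.0]
    spec[4] = [0.0, 0.0, 0.0, 1.0]
    rng = _rng(config.seed, "catalog")
    base_arr = np.array(list(BASES))
    cols = [
        rng.choice(4, size=config.n_donor_sites, p=spec[pos]) for pos in range(9)
    ]
    windows = ["".join(base_arr[c[i]] for c in cols) for i in range(config.n_donor_sites)]
    counts: dict[str, int] = {}
    for w in windows:
        counts[w] = counts.get(w, 0) + 1
    catalog = catalog_from_counts(
        counts, total_sites=config.n_donor_sites, source=f"simulated(seed={config.seed})"
    )
    return catalog, DonorPWM(freq=spec, derived_from="generator")


# ---------------------------------------------------------------------------
# ABO-like two-exon fixture (end-to-end surrogate)
# ---------------------------------------------------------------------------

#: catalog entries planted for the surrogate: the canonical donor window of
#: the fixture gene (with the worked-example count) and its cryptic donor,
#: plus unrelated filler windows.  Partial table: all other windows unseen.
FIXTURE_CATALOG_COUNTS = {
    "CAGGTGAGG": 2562,
    "AAGGTAAGT": 4000,
    "AAGGTGAGT": 1500,
    "CAGGTAAGT": 900,
}
FIXTURE_TOTAL_SITES = 189249

FIXTURE_FWD_PRIMER = "GGCTAACTAGAGAACCCACTGCTTA"
FIXTURE_REV_PRIMER = "CCAAACAAGACCAAGACAAGCATTA"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class AboLikeFixture:
    """End-to-end surrogate locus with ground truth known by construction."""

    model: GeneModel
    catalog: SpliceCatalog
    construct: MinigeneConstruct
    variant: str
    truth: dict = field(default_factory=dict)


def _fixture_exon1_cds() -> str:
    # 28 coding bases ending ...CAG so the donor window is CAG|GTGAGG;
    # codons: Met, Ala x7, Ala, then G opening the junction-spanning codon 10
    return "ATG" + "GCT" * 7 + "GCA" + "G"


def _fixture_exon2_cds() -> str:
    # Geometry fixed so that, for a retained length ≡ 2 (mod 3), the shifted
    # reading frame of exon 2 hits TAA at bases 31-33 while the unshifted
    # frame reads Leu/Asn there and terminates at bases 243-245.
    return "GT" + "AAA" + "CAC" * 8 + "C" + "TAA" + "AC" + "GAC" * 69 + "TAA"


def _fixture_intron(offset: int, intron_len: int) -> str:
    """Intron with the canonical donor start, a planted cryptic donor whose
    retained length is ``offset``, and a canonical AG end."""
    if offset < 9:
        raise ValueError("cryptic offset must be ≥ 9 in the surrogate intron")
    if offset + 8 > intron_len:
        raise ValueError(
            f"cryptic offset {offset} too close to the intron end ({intron_len})"
        )
    head = "GTGAGG" + "C" * (offset - 9) + "AAG"  # retained segment, length = offset
    cryptic = "GTAAGT"
    tail_len = intron_len - offset - len(cryptic) - 2
    tail = ("CCTCA" * (tail_len // 5 + 1))[:tail_len]
    return head + cryptic + tail + "AG"


def make_abo_like_fixture(
    config: SimulationConfig | None = None,
    cryptic_offset: int = 167,
    intron_len: int = 1500,
    intron5_keep: int = 660,
    intron3_keep: int = 360,
) -> AboLikeFixture:
    """Build the two-exon surrogate gene, its catalog and minigene construct.

    The gene mirrors the study locus's salient geometry: exon 1 contributes
    28 coding bases, the intron-1 donor window is CAG|GTGAGG, a cryptic donor
    sits at intron offset ``cryptic_offset`` (default 167, the validated
    insertion length), and the CDS is designed to diverge at codon 11 under
    retention.  With the default offset the retention consequence is
    p.Lys11Glufs*66 by construction.
    """
    config = config or SimulationConfig()
    if cryptic_offset + 6 > intron5_keep:
        raise ValueError(
            f"cryptic offset {cryptic_offset} not contained in the construct's "
            f"5' intron part ({intron5_keep} bp): retention would not be "
            "observable in the minigene"
        )
    utr5 = "GGTACCTCTAGA"
    utr3 = "GGATCCGAATTCGCATGCAAA"
    exon1 = utr5 + _fixture_exon1_cds()
    exon2 = _fixture_exon2_cds() + utr3
    intron = _fixture_intron(cryptic_offset, intron_len)
    sequence = exon1 + intron + exon2
    model = GeneModel(
        sequence=sequence,
        exons=[(1, len(exon1)), (len(exon1) + len(intron) + 1, len(sequence))],
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + 28 + 245,
        strand="+",
        name="ABO-like surrogate",
    )
    catalog = catalog_from_counts(
        FIXTURE_CATALOG_COUNTS,
        total_sites=FIXTURE_TOTAL_SITES,
        partial=True,
        source="fixture",
    )
    insert = truncate_intron(model, 1, intron5_keep, intron3_keep)
    construct = MinigeneConstruct(
        upstream_arm=FIXTURE_FWD_PRIMER + "GGATCCACCG",
        insert=insert,
        downstream_arm="CTCGAGTTAA"
        + FIXTURE_REV_PRIMER.translate(_COMPLEMENT)[::-1],
        fwd_primer=FIXTURE_FWD_PRIMER,
        rev_primer=FIXTURE_REV_PRIMER,
        intron5_len=intron5_keep,
        intron3_len=intron3_keep,
    )
    stop_offset = (cryptic_offset - 2) // 3 + 11 if cryptic_offset % 3 == 2 else None
    truth = {
        "variant": "c.28+5G>A",
        "wt_window": "CAGGTGAGG",
        "mut_window": "CAGGTGAAG",
        "cryptic_offset": cryptic_offset,
        "cryptic_window": "AAGGTAAGT",
        "expected_kind": "frameshift" if cryptic_offset % 3 else "in_frame",
        "first_changed_codon": 11,
        "stop_offset": stop_offset,
        "expected_hgvs_p": (
            f"p.Lys11Glufs*{stop_offset}" if stop_offset is not None else None
        ),
    }
    return AboLikeFixture(
        model=model,
        catalog=catalog,
        construct=construct,
        variant="c.28+5G>A",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Seven-exon diploid surrogate + amplicon reads
# ---------------------------------------------------------------------------

#: coding lengths of the seven exons of the study gene (1062 bp CDS total)
ABO_EXON_CODING_LENGTHS = (28, 70, 57, 48, 36, 135, 688)


def simulate_abo_gene_model(
    config: SimulationConfig | None = None, intron_len: int = 1200
) -> GeneModel:
    """A seven-exon surrogate with the study gene's coding exon lengths.

    Sequence is random but donor/acceptor dinucleotides are canonical and the
    reference base of every planted variant position matches its HGVS string,
    so the model can host the study's haplotype variant sets.
    """
    config = config or SimulationConfig()
    rng = _rng(config.seed, "gene")
    utr5 = 12
    base_arr = np.array(list(BASES))
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0

    def rand_seq(n: int) -> str:
        return "".join(base_arr[rng.integers(0, 4, size=n)])

    for i, coding in enumerate(ABO_EXON_CODING_LENGTHS):
        exon_len = coding + (utr5 if i == 0 else 0)
        exon = rand_seq(exon_len)
        if i == 0:
            exon = exon[:utr5] + "ATG" + exon[utr5 + 3:]
        exons.append((pos + 1, pos + exon_len))
        parts.append(exon)
        pos += exon_len
        if i < len(ABO_EXON_CODING_LENGTHS) - 1:
            intron = "GTAAGT" + rand_seq(intron_len - 8) + "AG"
            parts.append(intron)
            pos += intron_len
    sequence = "".join(parts)
    model = GeneModel(
        sequence=sequence,
        exons=exons,
        cds_start=utr5 + 1,
        cds_end=utr5 + sum(ABO_EXON_CODING_LENGTHS),
        strand="+",
        name="seven-exon surrogate",
    )
    # pin reference bases at the planted variant positions
    seq = list(model.sequence)
    for hap in config.planted_haplotypes:
        for v in hap:
            var = CVariant.parse(v)
            if var.kind in ("sub", "del") and var.ref:
                g = model.c_to_genomic(var.position)
                seq[g - 1] = var.ref[0]
    model.sequence = "".join(seq)
    return model


@dataclass
class DiploidTruth:
    """Ground truth of a simulated diploid read set."""

    het_sites: list[str]
    hom_sites: list[str]
    haplotype_sets: tuple[set[str], set[str]]
    fragments: list[tuple[int, int]]
    sites_by_fragment: dict[int, list[str]]
    read_haplotypes: list[int]


def _tile_fragments(length: int, n: int, overlap: int) -> list[tuple[int, int]]:
    if n == 1:
        return [(1, length)]
    frag_len = math.ceil((length + (n - 1) * overlap) / n)
    step = frag_len - overlap
    frags = []
    for i in range(n):
        start = 1 + i * step
        end = min(start + frag_len - 1, length)
        if i == n - 1:
            end = length
        frags.append((start, end))
    return frags


def simulate_diploid_reads(
    model: GeneModel, config: SimulationConfig
) -> tuple[list, DiploidTruth]:
    """Simulate per-fragment amplicon reads of a diploid carrier.

    Variants shared by both planted haplotypes are homozygous (no phase
    signal, excluded from reads); the rest are heterozygous.  Each read picks
    a haplotype uniformly and reports that haplotype's allele at every
    heterozygous site inside its fragment, flipped independently with the
    per-site error probability.
    """
    from .haplotype import ALT, REF, AmpliconRead

    set1 = {v.replace(" ", "") for v in config.planted_haplotypes[0]}
    set2 = {v.replace(" ", "") for v in config.planted_haplotypes[1]}
    hom = sorted(set1 & set2)
    het = sorted(set1 ^ set2)
    if not het:
        raise ValueError("planted haplotypes are identical: nothing to phase")
    positions = {
        v: model.c_to_genomic(CVariant.parse(v).position) for v in het
    }
    fragments = _tile_fragments(len(model.sequence), config.n_fragments, config.overlap_bp)
    sites_by_fragment = {
        i: [v for v in het if s <= positions[v] <= e]
        for i, (s, e) in enumerate(fragments)
    }
    uncovered = [v for v in het if all(v not in sites for sites in sites_by_fragment.values())]
    if uncovered:
        raise ValueError(f"variants outside all fragments: {uncovered}")
    for i in range(len(fragments) - 1):
        lo = fragments[i + 1][0]
        hi = fragments[i][1]
        shared = [v for v in het if lo <= positions[v] <= hi]
        if not shared:
            raise ValueError(
                f"config rejected: overlap between fragments {i} and {i + 1} "
                f"({lo}-{hi}) contains no heterozygous site"
            )
    rng = _rng(config.seed, "reads")
    reads = []
    read_haps: list[int] = []
    hap_sets = ({v for v in het if v in set1}, {v for v in het if v in set2})
    for frag_id, sites in sites_by_fragment.items():
        for _ in range(config.reads_per_fragment):
            h = int(rng.integers(0, 2))
            read_haps.append(h)
            obs = {}
            for site in sites:
                allele = ALT if site in hap_sets[h] else REF
                if rng.random() < config.per_site_error:
                    allele = REF if allele == ALT else ALT
                obs[site] = allele
            reads.append(AmpliconRead(fragment_id=frag_id, observations=obs))
    truth = DiploidTruth(
        het_sites=het,
        hom_sites=hom,
        haplotype_sets=(set1, set2),
        fragments=fragments,
        sites_by_fragment=sites_by_fragment,
        read_haplotypes=read_haps,
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Random minigene constructs (for property checks)
# ---------------------------------------------------------------------------

def simulate_construct(
    rng: np.random.Generator,
    min_offset: int = 9,
    max_offset: int = 400,
) -> tuple[MinigeneConstruct, int]:
    """A random intron-truncated construct with a known cryptic offset."""
    offset = int(rng.integers(min_offset, max_offset + 1))
    keep5 = int(rng.integers(offset + 6, offset + 206))
    keep3 = int(rng.integers(60, 400))
    intron_len = keep5 + keep3 + int(rng.integers(0, 800))
    fixture = make_abo_like_fixture(
        cryptic_offset=offset,
        intron_len=intron_len,
        intron5_keep=keep5,
        intron3_keep=keep3,
    )
    base_arr = np.array(list(BASES))
    up_link = "".join(base_arr[rng.integers(0, 4, size=int(rng.integers(5, 40)))])
    down_link = "".join(base_arr[rng.integers(0, 4, size=int(rng.integers(5, 40)))])
    construct = MinigeneConstruct(
        upstream_arm=FIXTURE_FWD_PRIMER + up_link,
        insert=fixture.construct.insert,
        downstream_arm=down_link + FIXTURE_REV_PRIMER.translate(_COMPLEMENT)[::-1],
        fwd_primer=FIXTURE_FWD_PRIMER,
        rev_primer=FIXTURE_REV_PRIMER,
        intron5_len=keep5,
        intron3_len=keep3,
    )
    return construct, offset
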