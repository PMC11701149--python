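"""5' donor splice-site 9-mer catalogs and the derived position frequency matrix.

A donor site is summarised by a 9-base window spanning the last three exonic
bases and the first six intronic bases (exon −3..−1, intron +1..+6).  Canonical
U2-type donors carry GT at intron +1/+2, i.e. at window positions 4-5.  A
:class:`SpliceCatalog` records how often each such 9-mer occurs among all GT
donor sites of a genome; genome-wide frequencies of these windows are the basis
of the SD-Score statistic (see :mod:`splicecall.sdscore`).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WINDOW_LEN = 9
#: window positions in splice-site convention: exon −3..−1, intron +1..+6
POSITION_LABELS = ("-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5", "+6")
#: window indices (0-based) of the intron +1/+2 dinucleotide
GT_SLICE = slice(3, 5)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidWindowError(ValueError):
    """Raised for sequences that are not valid donor 9-mer windows."""


def validate_window(seq: str, require_gt: bool = True) -> str:
    """Validate and normalise a donor window.

    Parameters
    ----------
    seq : str
        Candidate 9-mer (exon −3..−1 + intron +1..+6).
    require_gt : bool
        When True (default), reject windows whose intron +1/+2 is not GT.
        Mutant windows that destroy the GT dinucleotide may still be scored,
        in which case callers pass ``require_gt=False``.

    Returns
    -------
    str
        The upper-cased window.
    """
    w = str(seq).upper()
    if len(w) != WINDOW_LEN:
        raise InvalidWindowError(
            f"donor window must be {WINDOW_LEN} nt, got {len(w)} ({w!r})"
        )
    if any(b not in _BASE_INDEX for b in w):
        raise InvalidWindowError(f"donor window has non-ACGT characters: {w!r}")
    if require_gt and w[GT_SLICE] != "GT":
        raise InvalidWindowError(
            f"{w} is not a GT donor: intron +1/+2 is {w[GT_SLICE]!r}, expected 'GT'"
        )
    return w


@dataclass
class SpliceCatalog:
    """Genome-wide 9-mer donor-window count table.

    Parameters
    ----------
    counts : dict
        Map 9-mer window → number of GT donor sites carrying it.
    total_sites : int
        Total number of GT donor sites in the genome (N).  For a *partial*
        catalog this may exceed the sum of ``counts`` (windows not listed are
        treated as unseen, not as absent from the genome).
    pseudocount : float
        Numerator used in place of 0 for windows never observed, so that
        log-frequencies stay finite.  Must lie in (0, 1).
    partial : bool
        True when ``counts`` lists only a subset of the genome's windows.
    source : str
        Free-text provenance identifier.
    """

    counts: dict[str, int]
    total_sites: int
    pseudocount: float = 0.25
    partial: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.total_sites <= 0:
            raise ValueError(f"total_sites must be positive, got {self.total_sites}")
        if not (0 < self.pseudocount < 1):
            raise ValueError(f"pseudocount must lie in (0, 1), got {self.pseudocount}")
        clean: dict[str, int] = {}
        for key, n in self.counts.items():
            w = validate_window(key, require_gt=True)
            if n < 0:
                raise ValueError(f"negative count for {w}: {n}")
            clean[w] = int(n)
        self.counts = clean
        observed = sum(self.counts.values())
        if self.partial:
            if observed > self.total_sites:
                raise ValueError(
                    f"partial catalog counts sum to {observed} > total_sites "
                    f"{self.total_sites}"
                )
        elif observed != self.total_sites:
            raise ValueError(
                f"complete catalog counts sum to {observed} != total_sites "
                f"{self.total_sites}; declare the table partial if intended"
            )

    def count(self, window: str) -> int:
        return self.counts.get(validate_window(window, require_gt=False), 0)

    def frequency(self, window: str) -> float:
        """Genome-wide frequency of ``window``; pseudocount-floored if unseen."""
        n = self.count(window)
        numerator = n if n > 0 else self.pseudocount
        return numerator / self.total_sites

    @property
    def floor_log10(self) -> float:
        """log10 frequency assigned to a never-observed window."""
        return float(np.log10(self.pseudocount / self.total_sites))

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write the self-describing two-column catalog TSV."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#total_sites={self.total_sites}\n")
            fh.write(f"#pseudocount={self.pseudocount!r}\n")
            fh.write(f"#partial={'true' if self.partial else 'false'}\n")
            if self.source:
                fh.write(f"#source={self.source}\n")
            for window in sorted(self.counts):
                fh.write(f"{window}\t{self.counts[window]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceCatalog":
        path = Path(path)
        total_sites: int | None = None
        pseudocount = 0.25
        partial = False
        source = ""
        counts: dict[str, int] = {}
        for raw in path.read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "total_sites":
                    total_sites = int(value)
                elif key == "pseudocount":
                    pseudocount = float(value)
                elif key == "partial":
                    partial = value.strip().lower() in ("true", "1", "yes")
                elif key == "source":
                    source = value
                continue
            window, _, n = line.partition("\t")
            if not n:
                raise ValueError(f"malformed catalog line: {raw!r}")
            counts[window] = int(n)
        if total_sites is None:
            raise ValueError(f"{path}: missing '#total_sites=' header")
        return cls(
            counts=counts,
            total_sites=total_sites,
            pseudocount=pseudocount,
            partial=partial,
            source=source,
        )


def catalog_from_counts(
    counts: Mapping[str, int],
    total_sites: int,
    pseudocount: float = 0.25,
    partial: bool = False,
    source: str = "",
) -> SpliceCatalog:
    """Build a validated :class:`SpliceCatalog` from an in-memory count table."""
    return SpliceCatalog(
        counts=dict(counts),
        total_sites=total_sites,
        pseudocount=pseudocount,
        partial=partial,
        source=source,
    )


# ---------------------------------------------------------------------------
# Catalog construction from a genome + annotation
# ---------------------------------------------------------------------------

def _load_genome(genome) -> Mapping[str, str]:
    """Accept a FASTA path, a pyfaidx.Fasta, or a plain contig→sequence map."""
    if isinstance(genome, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    return genome


def _transcript_exons(annotation):
    """Yield (transcript_id, contig, strand, sorted exon intervals) per transcript.

    ``annotation`` is a GTF/GFF3 path (parsed with gffutils) or an iterable of
    ``(transcript_id, contig, strand, start, end)`` exon tuples (1-based
    inclusive coordinates).
    """
    if isinstance(annotation, (str, Path)):
        import gffutils

        db = gffutils.create_db(
            str(annotation),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        records = []
        for feat in db.features_of_type("exon"):
            attrs = feat.attributes
            tids = attrs.get("transcript_id") or attrs.get("Parent")
            if not tids:
                raise ValueError(
                    f"exon at {feat.seqid}:{feat.start}-{feat.end} has neither "
                    "transcript_id nor Parent"
                )
            for tid in tids:
                records.append((tid, feat.seqid, feat.strand, feat.start, feat.end))
    else:
        records = list(annotation)

    by_tx: dict[str, list] = {}
    for tid, contig, strand, start, end in records:
        by_tx.setdefault(tid, []).append((contig, strand, int(start), int(end)))
    for tid, exons in by_tx.items():
        contig = exons[0][0]
        strand = exons[0][1]
        intervals = sorted((s, e) for _, _, s, e in exons)
        yield tid, contig, strand, intervals


def donor_window_at(seq: str, exon_end: int, strand: str = "+") -> str:
    """Extract the 9-mer window for a donor whose exon/intron junction follows
    1-based position ``exon_end`` on the plus strand of ``seq``.

    For minus-strand donors ``exon_end`` is the 1-based genomic START of the
    exon (the junction precedes it in genome coordinates) and the window is
    reverse-complemented.
    """
    if strand == "+":
        lo, hi = exon_end - 3, exon_end + 6  # 0-based half-open
        if lo < 0 or hi > len(seq):
            raise ValueError(f"donor window at {exon_end}+ runs off the sequence")
        return str(seq[lo:hi]).upper()
    lo, hi = exon_end - 7, exon_end + 2
    if lo < 0 or hi > len(seq):
        raise ValueError(f"donor window at {exon_end}- runs off the sequence")
    return reverse_complement(str(seq[lo:hi]).upper())


def build_catalog_from_annotation(
    genome,
    annotation,
    pseudocount: float = 0.25,
    source: str = "annotation",
) -> SpliceCatalog:
    """Scan an annotation for internal donor sites and tally their 9-mers.

    One window is extracted per *unique* donor locus (contig, strand,
    junction); donor sites shared by several transcript isoforms count once.
    Sites whose intron does not begin with GT are skipped (and logged) — the
    catalog statistic is defined over GT donors only.
    """
    seqs = _load_genome(genome)
    seen: set[tuple[str, str, int]] = set()
    counts: dict[str, int] = {}
    n_non_gt = 0
    for tid, contig, strand, exons in _transcript_exons(annotation):
        if len(exons) < 2:
            continue
        try:
            contig_seq = seqs[contig]
        except KeyError as exc:
            raise KeyError(
                f"annotated contig {contig!r} (transcript {tid}) is missing from "
                "the genome sequences"
            ) from exc
        if strand == "+":
            junctions = [e for _, e in exons[:-1]]
        else:
            junctions = [s for s, _ in exons[1:]]
        for j in junctions:
            key = (contig, strand, j)
            if key in seen:
                continue
            seen.add(key)
            window = donor_window_at(contig_seq, j, strand)
            if window[GT_SLICE] != "GT":
                n_non_gt += 1
                logger.warning(
                    "skipping non-GT donor at %s:%s%s (window %s)",
                    contig, j, strand, window,
                )
                continue
            counts[window] = counts.get(window, 0) + 1
    if n_non_gt:
        logger.info("skipped %d non-GT donor site(s)", n_non_gt)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no GT donor sites found in the annotation")
    return SpliceCatalog(
        counts=counts, total_sites=total, pseudocount=pseudocount, source=source
    )


# ---------------------------------------------------------------------------
# Position frequency matrix
# ---------------------------------------------------------------------------

@dataclass
class DonorPWM:
    """Per-position base frequencies f(b, l) of a donor-window catalog.

    ``freq`` is a 9×4 array: rows follow :data:`POSITION_LABELS`, columns the
    bases A, C, G, T.  Each row sums to 1.
    """

    freq: np.ndarray
    derived_from: str = ""
    base_order: str = field(default=BASES, repr=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (WINDOW_LEN, 4):
            raise ValueError(f"PWM must be {WINDOW_LEN}x4, got {self.freq.shape}")
        if (self.freq < 0).any():
            raise ValueError("PWM frequencies must be non-negative")
        rowsum = self.freq.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError(f"PWM position frequencies must sum to 1, got {rowsum}")

    def freq_of(self, base: str, position_index: int) -> float:
        """f(base, l) with l a 0-based window index."""
        return float(self.freq[position_index, _BASE_INDEX[base.upper()]])


def pwm_from_catalog(catalog: SpliceCatalog) -> DonorPWM:
    """Count-weighted per-position base frequencies of the catalog's windows."""
    if not catalog.counts:
        raise ValueError("cannot derive a PWM from an empty catalog")
    freq = np.zeros((WINDOW_LEN, 4), dtype=float)
    for window, n in catalog.counts.items():
        for pos, base in enumerate(window):
            freq[pos, _BASE_INDEX[base]] += n
    freq /= freq.sum(axis=1, keepdims=True)
    return DonorPWM(freq=freq, derived_from=catalog.source or "catalog")
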