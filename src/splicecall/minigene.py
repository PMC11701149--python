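"""Minigene constructs and RT-PCR product-size prediction.

A minigene assay clones an exon–intron–exon fragment between vector arms,
transfects it, and reads splicing out as RT-PCR band sizes.  Because full
introns are often too large to clone, the insert's intron is truncated to a 5'
part joined directly to a 3' part; a retention-to-cryptic outcome is only
observable in the construct when the retained segment (and its donor window)
lies wholly inside the 5' part.

Band arithmetic: for a construct whose vector arms contribute fixed flanks,
the retention product exceeds the normal product by exactly the retained
length — the study's 348 bp vs 181 bp bands differ by the 167 bp insertion.
Absolute sizes depend on the (unpublished) arm lengths, so the difference is
the portable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import reverse_complement
from .transcript import GeneModel, SpliceOutcome


class PrimerError(ValueError):
    pass


@dataclass
class MinigeneConstruct:
    """Vector arms around a (possibly intron-truncated) two-exon insert."""

    upstream_arm: str
    insert: GeneModel
    downstream_arm: str
    fwd_primer: str = ""
    rev_primer: str = ""
    intron5_len: int | None = None  # length of the cloned 5' intron part
    intron3_len: int | None = None

    def __post_init__(self) -> None:
        self.upstream_arm = self.upstream_arm.upper()
        self.downstream_arm = self.downstream_arm.upper()
        self.fwd_primer = self.fwd_primer.upper()
        self.rev_primer = self.rev_primer.upper()

    def transcript_for(self, outcome: SpliceOutcome) -> str:
        """The RT-PCR template: vector exonic arms flank the spliced insert."""
        return self.upstream_arm + outcome.mrna + self.downstream_arm

    def retention_observable(self, offset: int, intron_index: int = 1) -> bool:
        """Whether a cryptic donor at ``offset`` is visible in this construct.

        The retained segment plus the candidate's donor window (+1..+6) must
        lie inside the cloned 5' intron part; otherwise the construct lacks
        the cryptic site and the outcome cannot be assayed.
        """
        if self.intron5_len is None:
            return True  # intron cloned whole
        return offset + 6 <= self.intron5_len


@dataclass
class RtPcrProduct:
    splice_patterns: list[str]
    length: int
    sequence: str

    @property
    def splice_pattern(self) -> str:
        return self.splice_patterns[0]


def _find_unique(template: str, primer: str, label: str) -> int:
    first = template.find(primer)
    if first < 0:
        raise PrimerError(f"{label} primer not found on transcript")
    if template.find(primer, first + 1) >= 0:
        raise PrimerError(f"{label} primer anneals at more than one position")
    return first


def truncate_intron(
    model: GeneModel, intron_index: int, keep5: int, keep3: int
) -> GeneModel:
    """Replace intron ``intron_index`` by its first ``keep5`` and last
    ``keep3`` bases joined directly — the standard minigene cloning shortcut.
    """
    s, e = model.intron_interval(intron_index)
    intron = model.intron_seq(intron_index)
    if keep5 + keep3 > len(intron):
        raise ValueError(
            f"kept parts ({keep5}+{keep3}) exceed intron length {len(intron)}"
        )
    new_intron = intron[:keep5] + intron[len(intron) - keep3:]
    removed = len(intron) - len(new_intron)
    seq = model.sequence[:s - 1] + new_intron + model.sequence[e:]
    exons = [
        (es, ee) if ee < s else (es - removed, ee - removed)
        for es, ee in model.exons
    ]
    return GeneModel(
        sequence=seq,
        exons=exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        strand=model.strand,
        name=model.name + f"|intron{intron_index}:{keep5}+{keep3}",
    )


def predict_products(
    construct: MinigeneConstruct,
    outcomes: list[SpliceOutcome],
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
) -> tuple[list[RtPcrProduct], list[str]]:
    """Predict RT-PCR bands for each splice outcome of a construct.

    Products are exact-match amplicons from the forward primer's 5' end to the
    reverse primer's annealing end on each outcome's transcript, deduplicated
    by sequence (the wild type's normal band and a mutant's residual normal
    band are one band).  Outcomes on which a primer does not anneal are
    returned in the second list as "no product".
    """
    fwd = (fwd_primer or construct.fwd_primer).upper()
    rev = (rev_primer or construct.rev_primer).upper()
    if not fwd or not rev:
        raise PrimerError("both primers are required")
    rev_site = reverse_complement(rev)
    products: list[RtPcrProduct] = []
    by_seq: dict[str, RtPcrProduct] = {}
    failures: list[str] = []
    for outcome in outcomes:
        template = construct.transcript_for(outcome)
        try:
            f0 = _find_unique(template, fwd, "forward")
            r0 = _find_unique(template, rev_site, "reverse")
        except PrimerError:
            failures.append(outcome.pattern)
            continue
        end = r0 + len(rev_site)
        if end <= f0:
            failures.append(outcome.pattern)
            continue
        seq = template[f0:end]
        if seq in by_seq:
            by_seq[seq].splice_patterns.append(outcome.pattern)
            continue
        product = RtPcrProduct(
            splice_patterns=[outcome.pattern], length=len(seq), sequence=seq
        )
        by_seq[seq] = product
        products.append(product)
    return products, failures


def gel_summary(products: list[RtPcrProduct], failures: list[str] = ()) -> str:
    """A text 'gel': one line per band, largest first."""
    lines = ["band\tlength_bp\tsplice_patterns"]
    for i, p in enumerate(sorted(products, key=lambda p: -p.length), 1):
        lines.append(f"{i}\t{p.length}\t{','.join(p.splice_patterns)}")
    for pattern in failures:
        lines.append(f"-\tno product\t{pattern}")
    return "\n".join(lines)
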