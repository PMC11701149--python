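"""Gene models, HGVS c. coordinates, splice outcomes and protein consequences.

A :class:`GeneModel` holds the sense-strand genomic sequence of a locus with
its exon intervals and the CDS span in transcript coordinates.  From a damaged
donor it enumerates candidate splice outcomes — partial intron retention up to
a cryptic donor, the normal transcript, and skipping of the exon upstream of
the donor — builds each mRNA, translates it, and renders the protein
consequence in HGVS p. notation (e.g. ``p.Lys11Glufs*66``: Lys at residue 11
replaced by Glu, frame shifted, stop at the 66th codon of the new frame
counting the changed residue as 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

_C_POSITION_RE = re.compile(r"^(?:c\.)?(\d+)([+-]\d+)?$")
_C_VARIANT_RE = re.compile(
    r"^(?:c\.)?(\d+)([+-]\d+)?"
    r"(?:([ACGT])>([ACGT])|del([ACGT]*)|ins([ACGT]+)|dup([ACGT]*))$"
)


@dataclass(frozen=True)
class CVariantPosition:
    """An HGVS c. position: CDS base plus optional intron offset.

    ``c.28+5`` → ``CVariantPosition(28, 5)``; exonic positions have offset 0.
    """

    cds_base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.cds_base < 1:
            raise ValueError(f"cds_base must be ≥ 1, got {self.cds_base}")

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return f"c.{self.cds_base}"
        sign = "+" if self.intron_offset > 0 else "-"
        return f"c.{self.cds_base}{sign}{abs(self.intron_offset)}"

    @classmethod
    def parse(cls, text: str) -> "CVariantPosition":
        m = _C_POSITION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse HGVS c. position: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


@dataclass(frozen=True)
class CVariant:
    """A parsed HGVS c. small variant (substitution, del, ins or dup)."""

    position: CVariantPosition
    kind: str  # "sub" | "del" | "ins" | "dup"
    ref: str = ""
    alt: str = ""

    @classmethod
    def parse(cls, text: str) -> "CVariant":
        m = _C_VARIANT_RE.match(text.strip().replace(" ", ""))
        if not m:
            raise ValueError(f"cannot parse HGVS c. variant: {text!r}")
        pos = CVariantPosition(int(m.group(1)), int(m.group(2) or 0))
        if m.group(3) is not None:
            return cls(pos, "sub", ref=m.group(3), alt=m.group(4))
        if m.group(5) is not None:
            return cls(pos, "del", ref=m.group(5))
        if m.group(6) is not None:
            return cls(pos, "ins", alt=m.group(6))
        return cls(pos, "dup", ref=m.group(7) or "")


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    """Sense-strand locus sequence plus exon structure and CDS span.

    Parameters
    ----------
    sequence : str
        Genomic sequence of the locus on the gene's sense strand (minus-strand
        genes are represented reverse-complemented, so splicing arithmetic is
        always left-to-right).
    exons : list of (start, end)
        1-based inclusive exon intervals in ``sequence`` coordinates,
        ascending and non-overlapping.
    cds_start, cds_end : int
        1-based positions of the first base of the start codon and the last
        base of the stop codon in *transcript* (spliced mRNA) coordinates.
    strand : str
        Original genomic strand, metadata only.
    """

    sequence: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).upper()
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        prev_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= len(self.sequence)):
                raise GeneModelError(f"exon ({s}, {e}) outside the sequence")
            if s <= prev_end:
                raise GeneModelError("exons must be ascending and non-overlapping")
            prev_end = e
        tx_len = sum(e - s + 1 for s, e in self.exons)
        if not (1 <= self.cds_start <= self.cds_end <= tx_len):
            raise GeneModelError(
                f"CDS span ({self.cds_start}, {self.cds_end}) outside the "
                f"{tx_len} nt transcript"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise GeneModelError("CDS length must be a multiple of 3")

    # ------------------------------------------------------------ structure
    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_seq(self, i: int) -> str:
        """Sequence of exon ``i`` (1-based)."""
        s, e = self.exons[i - 1]
        return self.sequence[s - 1:e]

    def intron_interval(self, i: int) -> tuple[int, int]:
        """1-based inclusive genomic interval of intron ``i`` (1-based)."""
        if not (1 <= i <= self.n_introns):
            raise GeneModelError(f"no intron {i} in a {len(self.exons)}-exon model")
        return self.exons[i - 1][1] + 1, self.exons[i][0] - 1

    def intron_seq(self, i: int) -> str:
        s, e = self.intron_interval(i)
        return self.sequence[s - 1:e]

    def transcript_seq(self) -> str:
        return "".join(self.exon_seq(i) for i in range(1, len(self.exons) + 1))

    def canonical_splice_flags(self) -> list[bool]:
        """Per intron, whether it begins GT and ends AG."""
        flags = []
        for i in range(1, self.n_introns + 1):
            intron = self.intron_seq(i)
            flags.append(intron[:2] == "GT" and intron[-2:] == "AG")
        return flags

    def cds_seq(self) -> str:
        return self.transcript_seq()[self.cds_start - 1:self.cds_end]

    def protein(self) -> str:
        """Wild-type protein, stop codon stripped."""
        aa = str(Seq(self.cds_seq()).translate())
        return aa[:-1] if aa.endswith("*") else aa

    # ---------------------------------------------------------- coordinates
    def transcript_to_genomic(self, tpos: int) -> int:
        """1-based transcript position → 1-based genomic position."""
        if tpos < 1:
            raise GeneModelError(f"transcript position must be ≥ 1, got {tpos}")
        remaining = tpos
        for s, e in self.exons:
            length = e - s + 1
            if remaining <= length:
                return s + remaining - 1
            remaining -= length
        raise GeneModelError(f"transcript position {tpos} beyond the transcript")

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Inverse of :meth:`transcript_to_genomic`; None for intronic bases."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                return offset + (gpos - s + 1)
            offset += e - s + 1
        return None

    def c_to_genomic(self, pos: CVariantPosition) -> int:
        """Map an HGVS c. position to a 1-based genomic (locus) coordinate."""
        tpos = self.cds_start + pos.cds_base - 1
        g = self.transcript_to_genomic(tpos)
        if pos.intron_offset == 0:
            return g
        exon_idx = next(
            i for i, (s, e) in enumerate(self.exons) if s <= g <= e
        )
        s, e = self.exons[exon_idx]
        if pos.intron_offset > 0:
            if g != e:
                raise GeneModelError(
                    f"{pos}: positive intron offsets require the last base of an "
                    f"exon; c.{pos.cds_base} maps inside exon {exon_idx + 1}"
                )
            if exon_idx + 1 >= len(self.exons):
                raise GeneModelError(f"{pos}: no intron downstream of the last exon")
            intron_len = self.exons[exon_idx + 1][0] - e - 1
            if pos.intron_offset > intron_len:
                raise GeneModelError(
                    f"{pos}: offset exceeds intron length {intron_len}"
                )
            return e + pos.intron_offset
        if g != s:
            raise GeneModelError(
                f"{pos}: negative intron offsets require the first base of an "
                f"exon; c.{pos.cds_base} maps inside exon {exon_idx + 1}"
            )
        if exon_idx == 0:
            raise GeneModelError(f"{pos}: no intron upstream of the first exon")
        intron_len = s - self.exons[exon_idx - 1][1] - 1
        if -pos.intron_offset > intron_len:
            raise GeneModelError(f"{pos}: offset exceeds intron length {intron_len}")
        return s + pos.intron_offset

    def genomic_to_c(self, gpos: int) -> CVariantPosition:
        """Inverse HGVS map; intronic bases get the nearer-exon anchor."""
        if not (1 <= gpos <= len(self.sequence)):
            raise GeneModelError(f"genomic position {gpos} outside the locus")
        tpos = self.genomic_to_transcript(gpos)
        if tpos is not None:
            return CVariantPosition(tpos - self.cds_start + 1)
        for i in range(1, self.n_introns + 1):
            s, e = self.intron_interval(i)
            if s <= gpos <= e:
                mid = s + (e - s) // 2
                if gpos <= mid:
                    anchor_t = self.genomic_to_transcript(s - 1)
                    return CVariantPosition(
                        anchor_t - self.cds_start + 1, gpos - s + 1
                    )
                anchor_t = self.genomic_to_transcript(e + 1)
                return CVariantPosition(anchor_t - self.cds_start + 1, gpos - e - 1)
        raise GeneModelError(f"position {gpos} in no exon or intron (flanking?)")

    # ------------------------------------------------------------ mutation
    def with_substitution(self, gpos: int, ref: str, alt: str) -> "GeneModel":
        """Return a copy of the model with a single-base substitution applied."""
        base = self.sequence[gpos - 1]
        if ref and base != ref.upper():
            raise GeneModelError(
                f"reference mismatch at position {gpos}: model has {base}, "
                f"variant states {ref}"
            )
        seq = self.sequence[:gpos - 1] + alt.upper() + self.sequence[gpos:]
        return GeneModel(
            sequence=seq,
            exons=list(self.exons),
            cds_start=self.cds_start,
            cds_end=self.cds_end,
            strand=self.strand,
            name=self.name,
        )

    def donor_window(self, intron_index: int) -> str:
        """9-mer donor window of intron ``intron_index`` (exon −3..−1 + intron +1..+6)."""
        s, e = self.intron_interval(intron_index)
        if s - 4 < 0 or s + 5 > len(self.sequence):
            raise GeneModelError("donor window runs off the locus")
        return self.sequence[s - 4:s + 5]

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "strand": self.strand,
            "sequence": self.sequence,
            "exons": [list(x) for x in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            sequence=d["sequence"],
            exons=[tuple(x) for x in d["exons"]],
            cds_start=d["cds_start"],
            cds_end=d["cds_end"],
            strand=d.get("strand", "+"),
            name=d.get("name", ""),
        )


# ---------------------------------------------------------------------------
# Splice outcomes
# ---------------------------------------------------------------------------

@dataclass
class ProteinConsequence:
    kind: str  # "no_change" | "synonymous" | "missense" | "nonsense" | "frameshift"
    first_changed_codon: int | None = None
    wt_residue: str = ""
    new_residue: str = ""
    stop_offset: int | None = None  # frameshift only; None when unresolved
    hgvs_p: str = "p.(=)"
    mutant_protein: str = ""


@dataclass
class SpliceOutcome:
    """One candidate splicing result with its mRNA and downstream consequence."""

    pattern: str  # "normal" | "retention_to_cryptic" | "exon_skip"
    mrna: str
    cds_start: int | None  # 1-based CDS start in ``mrna``; None if start lost
    retained_length: int = 0
    skipped_exon: int | None = None
    non_coding_start: bool = False
    protein: str = ""
    consequence: ProteinConsequence | None = None

    def summary(self) -> dict:
        return {
            "pattern": self.pattern,
            "mrna_length": len(self.mrna),
            "retained_length": self.retained_length,
            "skipped_exon": self.skipped_exon,
            "non_coding_start": self.non_coding_start,
            "protein_length": len(self.protein),
            "hgvs_p": self.consequence.hgvs_p if self.consequence else None,
            "consequence_kind": self.consequence.kind if self.consequence else None,
        }


def enumerate_splice_patterns(model, abolished_donor: int, cryptic=None) -> list:
    """Candidate splice outcomes when donor of intron ``abolished_donor`` is lost.

    Returns, in order: intron retention up to the cryptic donor (when a
    cryptic candidate is supplied), the normal transcript, and skipping of the
    exon immediately upstream of the damaged donor.  Each outcome carries its
    mRNA and the CDS start position within it; translation is done separately
    by :func:`translate_and_call`.
    """
    if not (1 <= abolished_donor <= model.n_introns):
        raise GeneModelError(
            f"no intron {abolished_donor} in a {len(model.exons)}-exon model"
        )
    exon_seqs = [model.exon_seq(i) for i in range(1, len(model.exons) + 1)]
    normal_mrna = "".join(exon_seqs)
    i = abolished_donor  # 1-based index of the exon upstream of the donor
    insertion_point = sum(len(s) for s in exon_seqs[:i])

    outcomes: list[SpliceOutcome] = []

    if cryptic is not None:
        retained = model.intron_seq(i)[:cryptic.offset]
        if len(retained) != cryptic.offset:
            raise GeneModelError(
                f"cryptic offset {cryptic.offset} exceeds intron {i} length"
            )
        mrna = (
            normal_mrna[:insertion_point] + retained + normal_mrna[insertion_point:]
        )
        if model.cds_start <= insertion_point:
            cds0 = model.cds_start
        else:
            cds0 = model.cds_start + len(retained)
        outcomes.append(
            SpliceOutcome(
                pattern="retention_to_cryptic",
                mrna=mrna,
                cds_start=cds0,
                retained_length=len(retained),
            )
        )

    outcomes.append(
        SpliceOutcome(pattern="normal", mrna=normal_mrna, cds_start=model.cds_start)
    )

    skip_start = sum(len(s) for s in exon_seqs[:i - 1])
    skip_end = skip_start + len(exon_seqs[i - 1])  # half-open transcript interval
    skip_mrna = normal_mrna[:skip_start] + normal_mrna[skip_end:]
    start0 = model.cds_start - 1  # 0-based
    if skip_start <= start0 < skip_end:
        cds0, lost = None, True
    elif start0 >= skip_end:
        cds0, lost = model.cds_start - len(exon_seqs[i - 1]), False
    else:
        cds0, lost = model.cds_start, False
    outcomes.append(
        SpliceOutcome(
            pattern="exon_skip",
            mrna=skip_mrna,
            cds_start=cds0,
            skipped_exon=i,
            non_coding_start=lost,
        )
    )
    return outcomes


def _translate_open(seq: str) -> tuple[str, bool]:
    """Translate to the first stop; returns (protein, stop_found)."""
    usable = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(usable).translate())
    idx = aa.find("*")
    if idx >= 0:
        return aa[:idx], True
    return aa, False


def aa3(residue: str) -> str:
    return AA3.get(residue, "Xaa")


def translate_and_call(outcome: SpliceOutcome, wt_protein: str) -> ProteinConsequence:
    """Translate an outcome's mRNA and call its protein consequence vs wild type.

    The comparison is a left-to-right scan to the first mismatching residue —
    sufficient for splice-driven frameshifts and matching the HGVS ``fs``
    convention.  For frameshifts, ``stop_offset`` counts new-frame codons from
    the first changed residue (inclusive) to the stop; a transcript running
    out of sequence before any stop leaves ``stop_offset`` unresolved (None).
    """
    if outcome.cds_start is None:
        cons = ProteinConsequence(
            kind="nonsense",
            first_changed_codon=1,
            wt_residue=wt_protein[:1],
            new_residue="",
            hgvs_p="p.0? (translation start lost)",
        )
        outcome.protein = ""
        outcome.consequence = cons
        return cons
    mut, stop_found = _translate_open(outcome.mrna[outcome.cds_start - 1:])
    outcome.protein = mut
    wt = wt_protein

    if mut == wt:
        kind = "no_change" if outcome.pattern == "normal" else "synonymous"
        cons = ProteinConsequence(kind=kind, hgvs_p="p.(=)", mutant_protein=mut)
        outcome.consequence = cons
        return cons

    mismatch = next(
        (k for k in range(min(len(mut), len(wt))) if mut[k] != wt[k]), None
    )
    if mismatch is None:
        if len(mut) < len(wt):
            pos = len(mut) + 1
            cons = ProteinConsequence(
                kind="nonsense",
                first_changed_codon=pos,
                wt_residue=wt[pos - 1],
                new_residue="*",
                hgvs_p=f"p.{aa3(wt[pos - 1])}{pos}Ter",
                mutant_protein=mut,
            )
        else:  # stop-loss extension; rendered as an fs-style extension
            pos = len(wt) + 1
            stop_off = (len(mut) - pos + 2) if stop_found else None
            cons = ProteinConsequence(
                kind="frameshift",
                first_changed_codon=pos,
                wt_residue="*",
                new_residue=mut[pos - 1],
                stop_offset=stop_off,
                hgvs_p=f"p.Ter{pos}{aa3(mut[pos - 1])}fs*"
                + (str(stop_off) if stop_off else "?"),
                mutant_protein=mut,
            )
        outcome.consequence = cons
        return cons

    pos = mismatch + 1
    wt_res, new_res = wt[mismatch], mut[mismatch]
    if len(mut) == len(wt) and mut[mismatch + 1:] == wt[mismatch + 1:]:
        cons = ProteinConsequence(
            kind="missense",
            first_changed_codon=pos,
            wt_residue=wt_res,
            new_residue=new_res,
            hgvs_p=f"p.{aa3(wt_res)}{pos}{aa3(new_res)}",
            mutant_protein=mut,
        )
        outcome.consequence = cons
        return cons

    stop_offset = (len(mut) - pos + 2) if stop_found else None
    hgvs = f"p.{aa3(wt_res)}{pos}{aa3(new_res)}fs*" + (
        str(stop_offset) if stop_offset is not None else "?"
    )
    cons = ProteinConsequence(
        kind="frameshift",
        first_changed_codon=pos,
        wt_residue=wt_res,
        new_residue=new_res,
        stop_offset=stop_offset,
        hgvs_p=hgvs,
        mutant_protein=mut,
    )
    outcome.consequence = cons
    return cons
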