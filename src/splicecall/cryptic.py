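"""Cryptic donor-site discovery in intronic sequence.

When a canonical donor is disabled by mutation, the spliceosome may fall back
on a nearby intronic GT that resembles a donor window; splicing from such a
*cryptic* donor retains the 5' segment of the intron in the mRNA.  The scanner
enumerates every GT dinucleotide in a region and scores its 9-mer context with
the catalog statistics; the default activation policy picks the *proximate*
candidate — the smallest retained length whose window has been observed at
least once genome-wide.

Offset convention: ``offset`` is the number of intron bases retained when the
candidate fires, i.e. the 1-based intron position of the last retained base;
the candidate's own +1 (the G of its GT) sits at intron position ``offset+1``.
A candidate at offset 167 produces a 167 bp insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import DonorPWM, SpliceCatalog, pwm_from_catalog
from .sdscore import DEFAULT_PSEUDOFREQ, ri_score, sd_score


@dataclass(frozen=True)
class CrypticCandidate:
    """One intronic GT donor candidate.

    ``offset``
        Retained-intron length if this donor fires (the candidate's +1 base is
        at 1-based intron position ``offset + 1``).
    ``window``
        The candidate's 9-mer donor window (−3..−1 context + GT + 4 bases).
    ``sd``, ``ri``
        Catalog SD-Score and information content of the window.
    """

    offset: int
    window: str
    sd: float
    ri: float


def scan_donors(
    sequence: str,
    region: tuple[int, int],
    catalog: SpliceCatalog,
    pwm: DonorPWM | None = None,
    pseudofreq: float = DEFAULT_PSEUDOFREQ,
) -> list[CrypticCandidate]:
    """Score every GT donor candidate in ``region`` of ``sequence``.

    Parameters
    ----------
    sequence : str
        The sequence containing the intron (typically the whole locus or the
        intron with flanking context; the −3..−1 part of a window may extend
        upstream of ``region``).
    region : (int, int)
        1-based inclusive interval to scan — normally the intron.  ``region``
        must start at the intron's first base for offsets to equal retained
        lengths.
    catalog : SpliceCatalog
        Source of SD-Scores; its PWM supplies Ri unless ``pwm`` is given.

    Returns
    -------
    list of :class:`CrypticCandidate`, sorted by offset.  The canonical donor
    itself (GT at the region start, offset 0) is not a cryptic candidate and
    is excluded.
    """
    seq = str(sequence).upper()
    start, end = region
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")
    if pwm is None:
        pwm = pwm_from_catalog(catalog)
    out: list[CrypticCandidate] = []
    for g in range(start, end + 1):  # 1-based position of a putative +1 base
        offset = g - start
        if offset < 1:
            continue
        if g + 1 > len(seq) or seq[g - 1] != "G" or seq[g] != "T":
            continue
        lo, hi = g - 4, g + 5  # 0-based half-open slice of the 9-mer window
        if lo < 0 or hi > len(seq):
            continue  # no full window context at the sequence edge
        window = seq[lo:hi]
        out.append(
            CrypticCandidate(
                offset=offset,
                window=window,
                sd=sd_score(window, catalog),
                ri=ri_score(window, pwm, pseudofreq),
            )
        )
    return out


def select_activated(
    candidates: list[CrypticCandidate],
    catalog: SpliceCatalog,
    policy: str = "nearest",
    min_sd: float | None = None,
) -> CrypticCandidate | None:
    """Pick the cryptic donor expected to fire, or None if nothing qualifies.

    Policies
    --------
    ``"nearest"`` (default)
        Smallest offset among candidates above threshold — the proximate
        downstream donor.
    ``"best"``
        Maximal SD-Score among candidates above threshold; ties broken toward
        the smaller offset.

    The threshold is ``min_sd`` when given, else "observed at least once in
    the catalog", i.e. SD-Score strictly above the unseen-window floor.
    """
    if not candidates:
        return None
    floor = catalog.floor_log10 if min_sd is None else min_sd
    passing = [c for c in candidates if c.sd > floor]
    if not passing:
        return None
    if policy == "nearest":
        return min(passing, key=lambda c: c.offset)
    if policy == "best":
        return max(passing, key=lambda c: (c.sd, -c.offset))
    raise ValueError(f"unknown selection policy {policy!r}")
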