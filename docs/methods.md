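# Methods

## Donor windows and the catalog

A 5' donor splice site is summarised by a 9-base window spanning exon
positions −3..−1 and intron positions +1..+6. The package restricts itself to
canonical U2-type GT donors: windows whose +1/+2 dinucleotide is not GT are
rejected at catalog ingestion (and counted non-GT donors are logged when
scanning an annotation), because the frequency statistic below is defined
over the population of GT donors. Acceptor sites, branch points and U12-type
introns are out of scope.

`build_catalog_from_annotation` extracts one window per *unique* donor locus
(contig, strand, junction): donor sites shared by several transcript isoforms
count once, since the statistic is a property of sites, not transcripts.
Minus-strand windows are reverse-complemented. The catalog stores the window
→ count map, the total GT-donor count N, and a pseudocount (default 0.25,
must be < 1) used in place of zero for unseen windows. A catalog may be
*partial* (a subset of windows with a larger stated N) — the form used for
worked examples and fixtures; partial tables treat absent windows as unseen,
not as absent from the genome. The TSV serialisation is self-describing
(`#total_sites=`, `#pseudocount=`, `#partial=` headers plus two columns) and
round-trips exactly.

## Scores

* **SD-Score**: log₁₀(n(w)/N), floored at log₁₀(pseudocount/N) when
  n(w) = 0. The floor keeps log-frequencies finite and is itself meaningful:
  with N = 189249 and pseudocount 0.25 it is −5.879, the score of any
  never-observed window. The score is monotone in the count at fixed N and
  never exceeds 0.
* **Ri (individual information content)**, in bits:
  Ri = Σₗ (2 + log₂ f(bₗ, l)) over the nine window positions, with PWM cells
  floored at a pseudofrequency (default 10⁻⁴) so unseen bases score a large
  but finite penalty. A window matching invariant positions everywhere scores
  18 bits; a uniform PWM gives 0 for every window.
* **CV (consensus value)**: the Shapiro–Senapathy-style score normalised to
  0–100 between the per-position minimum and maximum frequency sums; 100 for
  the per-position consensus window, 0 for the per-position minimum window.
  A fully uniform PWM has no span and is rejected.

The Ri and CV formulas are the package's own choices of the two canonical
splice-site measures that the upstream scoring convention reports alongside
the SD-Score but does not spell out; both are documented standards in the
splice-site literature (Schneider/Rogan information content;
Shapiro–Senapathy PWM score).

The PWM is derived from the catalog by count-weighted per-position base
frequencies; rows sum to 1 regardless of catalog skew.

## Decision cascade

For a variant scored as (ΔSD, mutant SD, ΔRi), with defaults
(−0.34, −2.9, −1.45):

1. ΔSD > −0.34 → **normal** (`delta_sd_pass`);
2. else mutant SD ≤ −2.9 → **aberrant** (`sd_rule`);
3. else ΔRi > −1.45 → **normal** (`ri_rule_normal`), else **aberrant**
   (`ri_rule_aberrant`).

Two deliberate choices: the second threshold is applied to the *mutant*
SD-Score (the only reading consistent with the cascade's logic), and boundary
equalities resolve to "aberrant" — conservative for a flagging tool, since
the published rule uses strict inequalities in both directions and leaves
equality undefined. Wild-type windows must be valid GT donors; mutant windows
may destroy the GT (they are flagged and necessarily score the unseen floor).
The cascade is total: every finite score triple fires exactly one rule.

## Cryptic donor scanning

Every GT dinucleotide in the scanned region (normally the mutant intron)
whose full 9-mer context lies on the sequence becomes a candidate, scored
with the same catalog SD-Score and Ri. The **offset** of a candidate is the
number of intron bases retained if it fires — equivalently the 1-based intron
position of the last retained base; the candidate's own +1 base sits at
offset + 1. The canonical donor at the region start (offset 0) is excluded.

Selection policy (default **nearest**): the smallest-offset candidate whose
SD-Score exceeds the activation threshold — by default "observed at least
once genome-wide", i.e. strictly above the pseudocount floor. This encodes
the proximity rule (the activated site is the proximate downstream donor),
with an optional absolute `min_sd` cutoff for partial catalogs and a
**best** (maximal SD) policy as an alternative. When nothing passes, the
scan reports "no activated cryptic donor" (None) rather than guessing.
Neural-network donor scores are not reimplemented; the catalog statistics
stand in for them throughout.

## Gene models, outcomes, consequences

`GeneModel` stores the sense-strand locus sequence, 1-based inclusive exon
intervals, and the CDS span in transcript coordinates; CDS length must be a
multiple of 3 and introns are checked (flagged, not rejected) for GT..AG.
Internally all slicing is 0-based half-open; every user-facing coordinate is
1-based (HGVS and GTF conventions). HGVS c. positions with intron offsets
(`c.28+5`) map to genomic coordinates and back; positive offsets are only
legal from an exon's last base, negative from an exon's first.

For a damaged donor of intron *i*, three outcomes are enumerated:

1. **retention_to_cryptic** (when a candidate is supplied): the intron's
   first `offset` bases are spliced into the mRNA between exons *i* and
   *i*+1, so mRNA length grows by exactly `offset`;
2. **normal**: the exact exon concatenation;
3. **exon_skip**: the exon immediately *upstream* of the damaged donor is
   dropped (only single-exon skips are enumerated). Skipping an exon that
   carries the start codon is returned but flagged `non_coding_start`.

Relative transcript abundances are not modelled; which outcomes a cell
actually produces (and in what ratio) is an experimental question.

Translation uses the standard nuclear code from the annotated start (no
alternative starts, no re-scanning). Consequence calling is a left-to-right
scan to the first mismatching residue — sufficient for splice-driven
frameshifts and matching the HGVS `fs` convention; no gapped alignment is
attempted. Frameshifts report `p.<Wt><pos><New>fs*<stop_offset>` with
`stop_offset` counting new-frame codons from the first changed residue
(inclusive) to the stop, so mutant protein length = first changed codon +
stop_offset − 2. A message with no in-frame stop leaves the offset
unresolved (`fs*?`). In-frame truncations render as `p.<Wt><pos>Ter`.
Note the off-by-one trap in prose descriptions of such alleles: a
`p.Lys11Glufs*66` protein has 75 residues, i.e. its *last residue* is 75 and
the stop occupies position 76; the package always reports the HGVS string
plus the mutant protein itself rather than a bare "termination position".

## Haplotype phasing and allele matching

Reads are per-fragment maps from heterozygous-site id to observed allele
(ref/alt). Phasing is greedy 2-clustering: seed the two clusters from the
best-covered site showing both alleles, then alternate majority-vote
consensus building and agreement-based reassignment (3 iterations; ties keep
the previous assignment, consensus vote ties are flagged ambiguous). Full
minimum-error-correction optimisation is out of scope — at amplicon depth
(tens of reads over ≤ ~15 sites) the greedy solution is the MEC solution in
practice. A fragment whose reads are identical at every site is declared
uninformative (error); a single read yields one supported and one empty,
flagged haplotype.

Consecutive fragments are stitched through the heterozygous sites shared in
their overlap: the orientation with the higher allele agreement wins; a tie
(no net phase signal) is an error naming the junction, and residual
disagreeing sites under the chosen orientation are resolved by total read
support. Homozygous variants carry no phase signal and are attached to both
haplotypes after stitching.

Allele matching is exact variant-set equality against a name → variant-set
table, falling back to the nearest allele(s) by symmetric difference with a
`novel, X-like (extra: …, missing: …)` label; ties report all tied names.
The shipped table holds only the two definitions the analysis needs
(`ABO*O.01.02`, `ABO*A2.01`), not a full allele registry.

## Minigene model

A construct is vector arms around a two-exon insert whose intron is the
concatenation of a 5' part and a 3' part (`truncate_intron`), mirroring how
large introns are cloned. The RT-PCR template for an outcome is
upstream arm + spliced mRNA + downstream arm; products are exact-match
amplicons from the forward primer to the reverse primer's annealing site.
Primers must match uniquely; an outcome on which a primer does not anneal
(or anneals twice) is reported "no product". Products are deduplicated by
sequence — a mutant's residual normal splice and the wild type's band are
one band. No annealing thermodynamics or band intensities are modelled:
this is product-size prediction, not PCR simulation.

Two identities follow by construction and are enforced as properties:
retention band − normal band = cryptic offset (exactly, for every construct),
and bands are invariant to intron sequence outside the retained segment. A
retention outcome is only *observable* when the retained segment plus the
candidate's donor context (offset + 6 bases) fits inside the 5' intron part.
Because the vector arm lengths of the published construct are not public,
absolute band sizes are fixture parameters; the band *difference* is the
portable, assayed quantity (the study's 348 vs 181 bp bands differ by the
167 bp insertion).

## Synthetic data: what it emulates, what it does not

All generators draw from named substreams of a single integer seed
(`SeedSequence([seed, stream_id])`), so identical configurations are
byte-identical regardless of stage order, and every generator returns a truth
record sufficient to score its downstream stage.

* **Catalog**: 9-mers drawn independently per position from a stylised human
  donor PWM (GT forced at +1/+2); default 5 000 sites. Positional
  independence is the PWM's own assumption; real donor sets carry
  inter-position dependence the generator does not emulate, which is why
  published Δ-scores from the original genome-wide catalog are treated as
  approximate corroboration, not exact targets.
* **Two-exon surrogate locus** (`make_abo_like_fixture`): exon 1 contributes
  28 coding bases ending in the donor window `CAG|GTGAGG`; a cryptic donor
  `AAG|GTAAGT` is planted at intron offset 167 (configurable); the CDS is
  engineered so retention diverges at codon 11 and — for offsets ≡ 2 mod 3 —
  stops at new-frame codon (offset−2)/3 + 11, giving `p.Lys11Glufs*66` at
  the default offset. Intron 1 defaults to 1.5 kb with a 660 + 360 bp
  minigene truncation, so the cryptic site is observable in the construct.
  The surrogate is deliberately short and synthetic; runs against the real
  reference sequence are a separate, user-supplied-download path.
* **Diploid reads**: a seven-exon surrogate with the real gene's coding exon
  lengths (28, 70, 57, 48, 36, 135, 688; 1.2 kb introns) hosts the study's
  two haplotype variant sets. Three fragments tile the locus with 1.2 kb
  overlaps (> 1 kb, as in the study design); each read picks a haplotype
  uniformly, reports alleles at the heterozygous sites inside its fragment,
  and flips each independently with the per-site error probability (default
  2%, a realistic consensus-read figure; depth 20 reads/fragment).
  Homopolymer indels, chimeras and coverage bias are not emulated, so
  passing tests demonstrate the phasing logic, not robustness to raw
  long-read artefacts. Configurations whose overlaps contain no heterozygous
  site are rejected rather than silently producing unjoinable fragments.

## Numerical and engineering choices

* Scores are floats; display rounding is 3 decimal places, matching the
  precision of the published worked examples.
* Strict inequalities everywhere in the cascade except the documented
  boundary-equality rule.
* Deterministic tie-breaks: nearest-policy ties are impossible (offsets
  unique); best-policy ties prefer the smaller offset; phasing assignment
  ties keep the previous cluster.
* Degenerate inputs fail loudly: empty catalogs, zero-span PWMs, regions
  outside sequences, intron offsets beyond intron length, reference-base
  mismatches, het-free overlaps.
* Problem sizes in the test suite (5 000-site catalogs, 200 phasing
  replicates, 100 random constructs) were chosen as the smallest sizes at
  which the checked properties are stable and meaningful.

## Known limitations

* The catalog PWM assumes positional independence; no dinucleotide or
  higher-order dependence.
* Only GT donors; no acceptor-side analysis, no branch-point model, no
  nonsense-mediated-decay prediction, no isoform quantification.
* Consequence calling is ungapped; complex rearrangements downstream of a
  splice defect would need proper alignment.
* Phasing assumes exactly two haplotypes and per-site independent errors.
* The published Δ-scores for the motivating variant (ΔSD −2.359, ΔRi −3.118)
  depend on the original genome-wide catalog, which is not redistributable;
  a rebuilt catalog reproduces the classification (aberrant) but not those
  exact numbers, and the package makes no attempt to.
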