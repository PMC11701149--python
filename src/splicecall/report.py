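"""End-to-end splice-impact report: score → classify → cryptic → transcript.

`run_report` chains the pipeline for one donor-region variant on one gene
model: locate the affected donor window, score wild-type vs mutant
(SD/Ri/CV), apply the decision cascade, and — only for variants called
aberrant — scan the intron for the activated cryptic donor, enumerate splice
outcomes on the mutant locus and call each protein consequence.  Variants
called normal skip the downstream stages (recorded as skipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import __version__
from .catalog import DonorPWM, SpliceCatalog, pwm_from_catalog
from .cryptic import CrypticCandidate, scan_donors, select_activated
from .sdscore import (
    DecisionThresholds,
    SpliceCall,
    SpliceImpactScores,
    classify,
    score_variant,
)
from .transcript import (
    CVariant,
    GeneModel,
    enumerate_splice_patterns,
    translate_and_call,
)

SCHEMA_VERSION = 1


class ReportError(ValueError):
    pass


@dataclass
class PipelineReport:
    variant: str
    gene: str
    scores: SpliceImpactScores | None = None
    call: SpliceCall | None = None
    cryptic: CrypticCandidate | None = None
    outcome_summaries: list[dict] = field(default_factory=list)
    outcomes: list = field(default_factory=list, repr=False)  # not serialized
    skipped_stages: list[str] = field(default_factory=list)
    stage_errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.stage_errors

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "variant": self.variant,
            "gene": self.gene,
            "scores": self.scores.to_dict() if self.scores else None,
            "call": (
                {"verdict": self.call.verdict, "rule_fired": self.call.rule_fired}
                if self.call
                else None
            ),
            "cryptic": (
                {
                    "offset": self.cryptic.offset,
                    "window": self.cryptic.window,
                    "sd": self.cryptic.sd,
                    "ri": self.cryptic.ri,
                }
                if self.cryptic
                else None
            ),
            "outcomes": self.outcome_summaries,
            "skipped_stages": self.skipped_stages,
            "stage_errors": self.stage_errors,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        scores = None
        if d.get("scores"):
            s = d["scores"]
            scores = SpliceImpactScores(
                wt_window=s["wt_window"],
                mut_window=s["mut_window"],
                sd_wt=s["sd_wt"],
                sd_mut=s["sd_mut"],
                ri_wt=s["ri_wt"],
                ri_mut=s["ri_mut"],
                cv_wt=s["cv_wt"],
                cv_mut=s["cv_mut"],
                mut_breaks_gt=s.get("mut_breaks_gt", False),
            )
        call = None
        if d.get("call"):
            call = SpliceCall(d["call"]["verdict"], d["call"]["rule_fired"])
        cryptic = None
        if d.get("cryptic"):
            c = d["cryptic"]
            cryptic = CrypticCandidate(c["offset"], c["window"], c["sd"], c["ri"])
        return cls(
            variant=d["variant"],
            gene=d.get("gene", ""),
            scores=scores,
            call=call,
            cryptic=cryptic,
            outcome_summaries=d.get("outcomes", []),
            skipped_stages=d.get("skipped_stages", []),
            stage_errors=d.get("stage_errors", {}),
            provenance=d.get("provenance", {}),
        )


def _affected_intron(model: GeneModel, var: CVariant) -> int:
    """Index of the donor whose 9-mer window contains the variant."""
    g = model.c_to_genomic(var.position)
    for i in range(1, model.n_introns + 1):
        s, _ = model.intron_interval(i)
        # window spans the exon's last 3 bases through intron +6
        if s - 3 <= g <= s + 5:
            return i
    raise ReportError(
        f"{var.position} (locus position {g}) lies in no donor 9-mer window"
    )


def run_report(
    model: GeneModel,
    variant: str,
    catalog: SpliceCatalog,
    thresholds: DecisionThresholds = DecisionThresholds(),
    pwm: DonorPWM | None = None,
    scan_policy: str = "nearest",
    seed: int | None = None,
) -> PipelineReport:
    """Run the full splice-impact pipeline for one donor-window variant."""
    report = PipelineReport(
        variant=variant,
        gene=model.name,
        provenance={
            "package_version": __version__,
            "catalog": catalog.source or "unnamed",
            "catalog_total_sites": catalog.total_sites,
            "thresholds": {
                "delta_sd_cut": thresholds.delta_sd_cut,
                "sd_mut_cut": thresholds.sd_mut_cut,
                "delta_ri_cut": thresholds.delta_ri_cut,
            },
            "scan_policy": scan_policy,
            "seed": seed,
        },
    )
    try:
        var = CVariant.parse(variant)
        if var.kind != "sub":
            raise ReportError(
                f"only substitutions are scored at donor windows, got {var.kind}"
            )
        intron_idx = _affected_intron(model, var)
        wt_window = model.donor_window(intron_idx)
        gpos = model.c_to_genomic(var.position)
        window_start = model.intron_interval(intron_idx)[0] - 3
        widx = gpos - window_start
        if wt_window[widx] != var.ref:
            raise ReportError(
                f"reference mismatch: window has {wt_window[widx]} at {var.position}, "
                f"variant states {var.ref}"
            )
        mut_window = wt_window[:widx] + var.alt + wt_window[widx + 1:]
    except (ValueError, ReportError) as exc:
        report.stage_errors["locate"] = str(exc)
        return report

    if pwm is None:
        pwm = pwm_from_catalog(catalog)

    try:
        report.scores = score_variant(wt_window, mut_window, catalog, pwm=pwm)
        report.call = classify(report.scores, thresholds)
    except ValueError as exc:
        report.stage_errors["score"] = str(exc)
        return report

    if report.call.verdict == "normal":
        report.skipped_stages = ["cryptic_scan", "transcript"]
        return report

    try:
        mut_model = model.with_substitution(gpos, var.ref, var.alt)
        intron_region = mut_model.intron_interval(intron_idx)
        candidates = scan_donors(mut_model.sequence, intron_region, catalog, pwm=pwm)
        report.cryptic = select_activated(candidates, catalog, policy=scan_policy)
    except ValueError as exc:
        report.stage_errors["cryptic_scan"] = str(exc)
        return report

    try:
        outcomes = enumerate_splice_patterns(mut_model, intron_idx, report.cryptic)
        wt_protein = model.protein()
        for outcome in outcomes:
            translate_and_call(outcome, wt_protein)
        report.outcome_summaries = [o.summary() for o in outcomes]
        report.outcomes = outcomes
    except ValueError as exc:
        report.stage_errors["transcript"] = str(exc)
    return report
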