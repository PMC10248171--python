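"""Rule-based toy variant callers and consensus-voting ensembles.

A caller here is a :class:`RuleSet`: per-type threshold conjunctions over the
site evidence vector, applied in a fixed evaluation order (DEL, INS, INV,
DUP, SNV).  A site is reported with the first covered type whose full
conjunction is satisfied.  This mirrors how production callers encode the
feature-to-mutation-type mappings — a deletion is reported where depth drops,
insert size stretches and split reads appear, and so on — while staying small
enough to reason about exactly.

An ensemble combines K rule sets by consensus voting: a site is reported only
when at least ``min_votes`` callers report it, with the type decided by
plurality (ties broken in the evaluation order).  Voting suppresses
false positives found by few callers but also discards true variants
detected by a minority — the false-negative cost of consensus.

Truth matching supports two semantics:

- ``match_types=True`` (default): a call at a truth site must also have the
  correct type to count as a true positive; a wrong-type call is a false
  positive and leaves the truth as a false negative.
- ``match_types=False``: detection-level matching — any call at a truth site
  is a true positive.  This is the semantics under which consensus voting
  obeys exact set algebra (at ``min_votes=K`` the consensus call set is
  contained in every caller's call set, so consensus FP <= each caller's FP
  and consensus FN >= each caller's FN), and it matches how TMB itself counts
  mutations irrespective of type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .cohort_sim import (
    SiteFeatures,
    SyntheticSample,
    ValidationError,
    VariantRecord,
    VTYPES,
)

__all__ = [
    "EVAL_ORDER",
    "RuleSet",
    "EnsembleSpec",
    "CallResult",
    "default_thresholds",
    "matched_ruleset",
    "snv_tuned_ruleset",
    "default_ensemble",
    "call_site",
    "call_sample",
    "consensus_call",
    "write_calls_vcf",
    "rulesets_to_yaml",
    "rulesets_from_yaml",
]

#: Fixed rule evaluation order; also the vote tie-break order.
EVAL_ORDER: tuple[str, ...] = ("DEL", "INS", "INV", "DUP", "SNV")


def default_thresholds() -> dict[str, dict[str, float]]:
    """Threshold conjunctions matched to the default feature signatures.

    With the default variant-allele-fraction floor of 0.2 the noise-free
    signatures of all five types fall strictly inside their own cell and
    outside every other, so a fully covering rule set with these thresholds
    is error-free in the noise-free limit.
    """
    return {
        "DEL": {"max_depth_ratio": 0.95, "min_insert_z": 0.3,
                "min_split_frac": 0.05},
        "INS": {"max_insert_z": -0.3, "min_split_frac": 0.05},
        "INV": {"min_split_frac": 0.05},   # plus orientation evidence
        "DUP": {"min_depth_ratio": 1.06, "min_split_frac": 0.05},
        "SNV": {"min_mismatch_frac": 0.1},
    }


@dataclass(frozen=True)
class RuleSet:
    """One toy caller: named per-type threshold conjunctions."""

    name: str
    thresholds: Mapping[str, Mapping[str, float]]
    covered_types: tuple[str, ...]

    def validate(self) -> None:
        if not self.covered_types:
            raise ValidationError("covered_types must be non-empty")
        for vt in self.covered_types:
            if vt not in VTYPES:
                raise ValidationError(f"unknown covered type {vt!r}")
            if vt not in self.thresholds:
                raise ValidationError(f"no thresholds for covered type {vt!r}")
            for key, val in self.thresholds[vt].items():
                if not _isfinite(val):
                    raise ValidationError(
                        f"threshold {vt}.{key} must be finite")


def _isfinite(x) -> bool:
    try:
        return abs(float(x)) < float("inf")
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class EnsembleSpec:
    """K rule sets plus the consensus quorum."""

    rulesets: tuple[RuleSet, ...]
    min_votes: int = 2

    def validate(self) -> None:
        if not self.rulesets:
            raise ValidationError("ensemble needs at least one ruleset")
        for rs in self.rulesets:
            rs.validate()
        if not 1 <= self.min_votes <= len(self.rulesets):
            raise ValidationError(
                f"min_votes must be in [1, {len(self.rulesets)}]")


def matched_ruleset(name: str = "matched",
                    covered_types: Sequence[str] = VTYPES,
                    overrides: Mapping[str, Mapping[str, float]] | None = None
                    ) -> RuleSet:
    """A caller using the default thresholds over the given type coverage."""
    thr = default_thresholds()
    if overrides:
        for vt, tdict in overrides.items():
            thr.setdefault(vt, {}).update(tdict)
    rs = RuleSet(name=name, thresholds=thr,
                 covered_types=tuple(covered_types))
    rs.validate()
    return rs


def snv_tuned_ruleset() -> RuleSet:
    """A caller whose rules cover SNVs only.

    The archetype of a caller tuned on the common mutation class: accurate on
    SNV-rich samples, blind to indels and structural events — the source of
    composition-driven error-rate swings across a cohort.
    """
    return matched_ruleset(name="snv_tuned", covered_types=("SNV",))


def default_ensemble(min_votes: int = 2) -> EnsembleSpec:
    """Three overlapping callers sharing the same fundamental thresholds.

    Coverage differs — one full-spectrum caller, one small-variant caller,
    one depth-oriented caller — while the threshold rules overlap heavily,
    mirroring real toolkits whose fundamental rule components are shared.
    """
    a = matched_ruleset(name="flowA_full", covered_types=VTYPES)
    b = matched_ruleset(name="flowB_small", covered_types=("SNV", "INS", "DEL"))
    c = matched_ruleset(name="flowC_depth", covered_types=("SNV", "DEL", "DUP"))
    ens = EnsembleSpec(rulesets=(a, b, c), min_votes=min_votes)
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# single-site and single-sample calling
# ---------------------------------------------------------------------------

def _satisfies(vt: str, f: SiteFeatures, thr: Mapping[str, float]) -> bool:
    if vt == "DEL":
        return (f.depth_ratio <= thr["max_depth_ratio"]
                and f.insert_z >= thr["min_insert_z"]
                and f.split_frac >= thr["min_split_frac"])
    if vt == "INS":
        return (f.insert_z <= thr["max_insert_z"]
                and f.split_frac >= thr["min_split_frac"])
    if vt == "INV":
        return (f.orientation_flag
                and f.split_frac >= thr["min_split_frac"])
    if vt == "DUP":
        return (f.depth_ratio >= thr["min_depth_ratio"]
                and f.split_frac >= thr["min_split_frac"])
    if vt == "SNV":
        return f.mismatch_frac >= thr["min_mismatch_frac"]
    raise ValidationError(f"unknown vtype {vt!r}")  # pragma: no cover


def call_site(features: SiteFeatures, ruleset: RuleSet) -> str | None:
    """Report the first covered type whose conjunction holds, else None."""
    for vt in EVAL_ORDER:
        if vt in ruleset.covered_types and _satisfies(
                vt, features, ruleset.thresholds[vt]):
            return vt
    return None


@dataclass
class CallResult:
    """Calls for one sample, classified against the truth."""

    sample_id: str
    calls: list[VariantRecord]
    tp: int
    fp: int
    fn: int
    n_true: int
    per_type: dict[str, dict[str, int]]
    rejected: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_true:
            raise ValidationError("tp + fn must equal the truth count")
        if self.tp > len(self.calls):
            raise ValidationError("tp cannot exceed the number of calls")
        if self.fp != len(self.calls) - self.tp:
            raise ValidationError("fp must equal |calls| - tp")


def _classify(sample: SyntheticSample,
              truth_decisions: list[str | None],
              bg_decisions: list[str | None],
              match_types: bool,
              match_mode: str,
              tol_bp: int,
              sample_id: str | None = None,
              rejected: list[VariantRecord] | None = None) -> CallResult:
    if match_mode not in ("site_id", "interval"):
        raise ValidationError(f"unknown match_mode {match_mode!r}")
    n_true = len(sample.truth)
    calls: list[VariantRecord] = []
    tp = 0
    per_type = {vt: {"tp": 0, "fp": 0, "fn": 0} for vt in VTYPES}
    matched_truth = [False] * n_true

    # first pass: decisions at truth sites
    pending_fp: list[VariantRecord] = []
    for i, (truth, decision) in enumerate(zip(sample.truth, truth_decisions)):
        if decision is None:
            continue
        rec = VariantRecord(site_id=truth.site_id, position=truth.position,
                            vtype=decision, length=1, vaf=1.0)
        calls.append(rec)
        if decision == truth.vtype or not match_types:
            tp += 1
            matched_truth[i] = True
            per_type[truth.vtype]["tp"] += 1
        else:
            pending_fp.append(rec)

    # second pass: decisions at background sites
    by_position = {t.position: i for i, t in enumerate(sample.truth)}
    for j, decision in enumerate(bg_decisions):
        if decision is None:
            continue
        pos = int(sample.background_positions[j])
        rec = VariantRecord(site_id=n_true + j, position=pos,
                            vtype=decision, length=1, vaf=1.0)
        calls.append(rec)
        hit = None
        if match_mode == "interval":
            # breakpoint-tolerant rescue of near-miss calls
            for q in range(pos - tol_bp, pos + tol_bp + 1):
                i = by_position.get(q)
                if i is None or matched_truth[i]:
                    continue
                if sample.truth[i].vtype == decision or not match_types:
                    hit = i
                    break
        if hit is not None:
            tp += 1
            matched_truth[hit] = True
            per_type[sample.truth[hit].vtype]["tp"] += 1
        else:
            pending_fp.append(rec)

    for rec in pending_fp:
        per_type[rec.vtype]["fp"] += 1
    for i, t in enumerate(sample.truth):
        if not matched_truth[i]:
            per_type[t.vtype]["fn"] += 1

    fp = len(calls) - tp
    fn = n_true - tp
    return CallResult(sample_id=sample_id or sample.sample_id, calls=calls,
                      tp=tp, fp=fp, fn=fn, n_true=n_true, per_type=per_type,
                      rejected=rejected or [])


def call_sample(sample: SyntheticSample, ruleset: RuleSet,
                match_types: bool = True, match_mode: str = "site_id",
                tol_bp: int = 10) -> CallResult:
    """Apply one caller to every variant and background site of a sample."""
    ruleset.validate()
    truth_decisions = [call_site(f, ruleset) for f in sample.variant_features]
    bg_decisions = [call_site(f, ruleset) for f in sample.background_features]
    return _classify(sample, truth_decisions, bg_decisions, match_types,
                     match_mode, tol_bp)


def _plurality(votes: list[str]) -> str:
    counts: dict[str, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    for vt in EVAL_ORDER:  # fixed tie-break
        if counts.get(vt, 0) == best:
            return vt
    raise RuntimeError("unreachable")  # pragma: no cover


def consensus_call(sample: SyntheticSample, ens: EnsembleSpec,
                   match_types: bool = True, match_mode: str = "site_id",
                   tol_bp: int = 10) -> CallResult:
    """Consensus voting across the ensemble's callers.

    A site is reported iff at least ``min_votes`` callers report it; the
    reported type is the plurality among the reporting callers.  Candidate
    calls below the quorum are kept on ``result.rejected`` (they carry the
    ``consensus_rejected`` FILTER in VCF output).
    """
    ens.validate()
    rejected: list[VariantRecord] = []

    def vote(features: SiteFeatures) -> tuple[str | None, list[str]]:
        votes = [d for rs in ens.rulesets
                 if (d := call_site(features, rs)) is not None]
        if len(votes) >= ens.min_votes:
            return _plurality(votes), votes
        return None, votes

    truth_decisions: list[str | None] = []
    for truth, f in zip(sample.truth, sample.variant_features):
        d, votes = vote(f)
        truth_decisions.append(d)
        if d is None and votes:
            rejected.append(VariantRecord(site_id=truth.site_id,
                                          position=truth.position,
                                          vtype=_plurality(votes),
                                          length=1, vaf=1.0))
    n_true = len(sample.truth)
    bg_decisions: list[str | None] = []
    for j, f in enumerate(sample.background_features):
        d, votes = vote(f)
        bg_decisions.append(d)
        if d is None and votes:
            rejected.append(VariantRecord(
                site_id=n_true + j,
                position=int(sample.background_positions[j]),
                vtype=_plurality(votes), length=1, vaf=1.0))
    return _classify(sample, truth_decisions, bg_decisions, match_types,
                     match_mode, tol_bp, rejected=rejected)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_VCF_CALLS_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrS,length={length}>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Called variant type">
##FILTER=<ID=consensus_rejected,Description="Below the consensus voting quorum">
##ALT=<ID=SNV,Description="Single-nucleotide variant">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=DUP,Description="Tandem duplication">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_calls_vcf(result: CallResult, region_length: int, path) -> None:
    """Write PASS calls plus consensus-rejected candidates as VCF 4.2."""
    rows = [(c.position, c.site_id, c.vtype, "PASS") for c in result.calls]
    rows += [(c.position, c.site_id, c.vtype, "consensus_rejected")
             for c in result.rejected]
    rows.sort()
    with open(path, "w") as fh:
        fh.write(_VCF_CALLS_HEADER.format(length=region_length))
        for pos, sid, vt, filt in rows:
            fh.write(f"chrS\t{pos}\tcall{sid}\tN\t<{vt}>\t.\t{filt}\t"
                     f"SVTYPE={vt}\n")


def rulesets_to_yaml(rulesets: Sequence[RuleSet], path) -> None:
    payload = [
        {"name": rs.name,
         "covered_types": list(rs.covered_types),
         "thresholds": {vt: dict(t) for vt, t in rs.thresholds.items()}}
        for rs in rulesets
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def rulesets_from_yaml(path) -> list[RuleSet]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for item in payload:
        rs = RuleSet(name=item["name"],
                     thresholds=item["thresholds"],
                     covered_types=tuple(item["covered_types"]))
        rs.validate()
        out.append(rs)
    return out
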