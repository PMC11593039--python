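"""Decision-level fusion of height-loss-ratio morphometry and detector scores.

Four per-vertebra classification strategies:

* **Method 1 (HLR only)** — positive iff HLR >= tau.
* **Method 2 (detector only)** — positive iff confidence >= theta_pos.
* **Method 3 (HLR + detector, positive override)** — HLR call, but a
  vertebra the HLR calls negative is reclassified positive when the
  detector's confidence clears theta_pos.  Positives are a superset of
  Method 1's, so sensitivity can only rise and specificity only fall.
* **Method 4 (HLR + detector, negative override)** — HLR call, but a
  vertebra the HLR calls positive is negated when the detector shows
  (almost) nothing: positive iff HLR >= tau AND confidence >= theta_neg.
  Positives are a subset of Method 1's, so specificity can only rise.

The negation criterion is deliberately weaker than the Method-2 operating
point (theta_neg <= theta_pos); by default any matched detection at all
(confidence > 0) blocks negation.

Each method also defines a continuous fused score on [0, 1] whose
thresholding at the method's operating point reproduces the binary call,
enabling ROC analysis: M1 -> HLR; M2 -> confidence;
M3 -> max(1{HLR >= tau}, confidence); M4 -> confidence if HLR >= tau else 0.
Ties at thresholds resolve as ">=" throughout, matching the closed lower
bounds of the Genant grade intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

from .detect_io import VertebraScore
from .errors import AlignmentError, InvalidInputError
from .metrics import ConfusionCounts
from .morphometry import MorphometryRecord

__all__ = ["FusionConfig", "FusionDecision", "classify", "classify_cohort", "METHOD_NAMES"]

METHOD_NAMES = {
    1: "HLR only",
    2: "DL only",
    3: "HLR + DL, positive",
    4: "HLR + DL, negative",
}

#: "any detection box exists" expressed as a confidence threshold
ANY_DETECTION = 1e-6


@dataclass(frozen=True)
class FusionConfig:
    """Thresholds and method selection for decision fusion.

    hlr_threshold (tau): HLR diagnostic cut, default 0.25.
    dl_positive_threshold (theta_pos): detector operating point for
        positive calls/overrides, default 0.5.
    dl_negation_threshold (theta_neg): the weaker criterion Method 4 uses to
        keep an HLR-positive vertebra positive; default ``ANY_DETECTION``
        (any matched box blocks negation).  Setting it to 0 disables
        negation entirely (Method 4 degenerates to Method 1).
    """

    method: int = 3
    hlr_threshold: float = 0.25
    dl_positive_threshold: float = 0.5
    dl_negation_threshold: float = ANY_DETECTION

    def __post_init__(self) -> None:
        if self.method not in (1, 2, 3, 4):
            raise InvalidInputError(f"method must be 1-4, got {self.method}")
        for name in ("hlr_threshold", "dl_positive_threshold", "dl_negation_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0,1], got {v}")
        if self.dl_negation_threshold > self.dl_positive_threshold:
            raise InvalidInputError("theta_neg must not exceed theta_pos")

    @property
    def operating_point(self) -> float:
        """Threshold on the fused score that reproduces the binary call."""
        return {
            1: self.hlr_threshold,
            2: self.dl_positive_threshold,
            3: self.dl_positive_threshold,
            4: self.dl_negation_threshold,
        }[self.method]


@dataclass(frozen=True)
class FusionDecision:
    """Binary call for one vertebra with provenance and a fused score."""

    vertebra_id: Hashable
    method: int
    positive: bool
    provenance: str  # which rule fired: "hlr", "dl" or "override"
    fused_score: float


def classify(
    record: MorphometryRecord,
    score: VertebraScore | None,
    cfg: FusionConfig,
    vertebra_id: Hashable | None = None,
) -> FusionDecision:
    """Apply one fusion method to one vertebra.

    ``score`` may be omitted only for Method 1.  The returned decision
    satisfies ``positive == (fused_score >= cfg.operating_point)`` except in
    the degenerate all-negative branch of Method 4 (fused score pinned to 0).
    """
    if score is None and cfg.method != 1:
        raise InvalidInputError(f"method {cfg.method} requires a detector score")
    vid = vertebra_id if vertebra_id is not None else (
        score.vertebra_id if score is not None else record.vertebra_label
    )
    tau = cfg.hlr_threshold
    hlr_pos = record.hlr >= tau
    conf = score.dl_confidence if score is not None else 0.0

    if cfg.method == 1:
        return FusionDecision(vid, 1, hlr_pos, "hlr", record.hlr)
    if cfg.method == 2:
        return FusionDecision(vid, 2, conf >= cfg.dl_positive_threshold, "dl", conf)
    if cfg.method == 3:
        fused = 1.0 if hlr_pos else conf
        if hlr_pos:
            return FusionDecision(vid, 3, True, "hlr", fused)
        dl_pos = conf >= cfg.dl_positive_threshold
        return FusionDecision(vid, 3, dl_pos, "override" if dl_pos else "hlr", fused)
    # Method 4
    fused = conf if hlr_pos else 0.0
    if not hlr_pos:
        return FusionDecision(vid, 4, False, "hlr", fused)
    negated = conf < cfg.dl_negation_threshold
    return FusionDecision(vid, 4, not negated, "override" if negated else "hlr", fused)


@dataclass(frozen=True)
class CohortResult:
    decisions: list[FusionDecision]
    counts: ConfusionCounts
    fused_scores: dict = field(default_factory=dict)


def classify_cohort(
    records: Mapping[Hashable, MorphometryRecord] | Sequence[MorphometryRecord],
    scores: Mapping[Hashable, VertebraScore] | Sequence[VertebraScore] | None,
    truth: Mapping[Hashable, bool],
    cfg: FusionConfig,
) -> CohortResult:
    """Classify every vertebra in a cohort and tally the confusion counts.

    ``records``, ``scores`` and ``truth`` must cover the same vertebra ids
    (records/scores may be given as sequences, keyed by their own labels/ids).
    """
    if not isinstance(records, Mapping):
        records = {r.vertebra_label: r for r in records}
    if scores is not None and not isinstance(scores, Mapping):
        scores = {s.vertebra_id: s for s in scores}

    ids = set(truth)
    missing_rec = sorted(map(str, ids - set(records)))
    if missing_rec:
        raise AlignmentError(f"no morphometry record for vertebrae: {missing_rec[:10]}")
    if cfg.method != 1:
        if scores is None:
            raise InvalidInputError(f"method {cfg.method} requires detector scores")
        missing_sc = sorted(map(str, ids - set(scores)))
        if missing_sc:
            raise AlignmentError(f"no detector score for vertebrae: {missing_sc[:10]}")

    decisions, fused = [], {}
    tp = tn = fp = fn = 0
    for vid in truth:
        sc = scores.get(vid) if scores is not None else None
        d = classify(records[vid], sc, cfg, vertebra_id=vid)
        decisions.append(d)
        fused[vid] = d.fused_score
        if truth[vid]:
            tp += d.positive
            fn += not d.positive
        else:
            fp += d.positive
            tn += not d.positive
    return CohortResult(decisions, ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn), fused)
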