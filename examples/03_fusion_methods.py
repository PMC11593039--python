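"""The four fusion strategies on two instructive vertebrae.

Vertebra A: uniform (crush-like) collapse — the height loss *ratio* is
normal, but the detector sees the cortical deformity with confidence 0.82.
Vertebra B: HLR of 32.05% (moderate) but the detector found nothing,
suggesting a tall-normal body rather than a fracture.
"""

from spinemorph import FusionConfig, classify
from spinemorph.detect_io import VertebraScore
from spinemorph.morphometry import MorphometryRecord, genant_grade


def make_record(label, hlr):
    hp = 25.0
    return MorphometryRecord(label, (1 - hlr) * hp, hp, hp, hlr,
                             genant_grade(hlr), hlr >= 0.25)


cases = {
    "A (ratio-blind fracture)": (make_record("A", 0.10), VertebraScore("A", 0.82)),
    "B (tall normal, high ratio)": (make_record("B", 0.3205), VertebraScore("B", 0.0)),
}

for name, (rec, score) in cases.items():
    print(f"\n{name}: HLR={rec.hlr:.1%}, detector confidence={score.dl_confidence:.2f}")
    for method in (1, 2, 3, 4):
        d = classify(rec, score, FusionConfig(method=method))
        print(f"  method {method}: {'POSITIVE' if d.positive else 'negative':8s} "
              f"(rule: {d.provenance}, fused score {d.fused_score:.2f})")

# Method 3 rescues the ratio-blind fracture (A) via the detector override;
# Method 4 suppresses the likely false positive (B) because no box supports
# the high ratio.
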