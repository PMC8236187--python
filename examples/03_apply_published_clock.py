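"""Apply published clock coefficient sets, including age-transformed ones.

Builds two small coefficient files — a direct dpc-scale clock and a
years-scale clock with the log-linear output transform used by the
multi-tissue clock — applies both to one sample, and converts all
predictions onto the common days-post-conception scale.
"""

import tempfile
from pathlib import Path

import numpy as np

import devclock as dc

tmp = Path(tempfile.mkdtemp())

(tmp / "fetal.tsv").write_text(
    "#name=fetal_direct\n#output_unit=dpc\n"
    "term\tcoefficient\n(Intercept)\t60\ncgA\t80\ncgB\t-20\n"
)
(tmp / "multitissue.tsv").write_text(
    "#name=multi_tissue_style\n#output_unit=years\n"
    "#transform=horvath_log_linear\n#adult_age=20\n"
    "term\tcoefficient\n(Intercept)\t-1.2\ncgA\t1.1\ncgB\t-0.6\n"
)

betas = dc.BetaMatrix(["cgA", "cgB"], ["sample1"], np.array([[0.62], [0.35]]))

for path in ("fetal.tsv", "multitissue.tsv"):
    clock = dc.read_clock(tmp / path)
    res = dc.predict_age(betas, clock)[0]
    stage = dc.classify_stage(res.predicted_age_dpc)
    print(
        f"{clock.name:18s} raw={res.raw_score:8.3f} "
        f"native={res.predicted_age_native:8.2f} {clock.output_unit.value:8s} "
        f"dpc={res.predicted_age_dpc:9.1f}  stage={stage}"
    )

# The dpc-scale clock reads off the linear predictor directly; the
# years-scale clock first inverts the log-linear transform (negative raw
# scores map exponentially toward -1 year = conception) and then converts
# years to dpc via years*365 + 280.
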