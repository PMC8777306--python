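"""Construction of the packaged stand-in trial network.

The real trial network of non-insulin glucose-lowering drugs is described in
the literature only by its aggregates: 161 trials, 24 drugs, 7 WHO-ATC
level-5 classes, 210,046 randomized participants.  This module deterministically
synthesizes a network matching those aggregates exactly, with the qualitative
features the hierarchical model's behaviour depends on:

- a right-skewed trials-per-drug distribution (several single-trial drugs, a
  few drugs with >= 15 trials);
- class sizes from one drug (biguanides) to six (DPP-4 inhibitors);
- right-skewed enrollments with a minimum of 300, large for outcome-trial
  programmes (GLP-1 analogues, SGLT-2 inhibitors, DPP-4 inhibitors) and small
  for the sulfonylurea/meglitinide drugs;
- one drug (taspoglutide) represented by a single small trial.

The result is frozen in ``data/default_network.csv``; regenerating it with
:func:`build_standin_frame` reproduces the file bit-for-bit.  Drug codes are
real ATC level-7 codes except taspoglutide, which never received one and
carries the synthetic placeholder ``A10BX90``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TARGET_TRIALS = 161
TARGET_ENROLLMENT = 210_046
MIN_ENROLLMENT = 300
_BUILD_SEED = 20210818  # frozen; changing it changes the packaged network

# (drug_name, drug_code, class_code, n_trials, size_class)
_ALLOCATION = [
    ("metformin", "A10BA02", "A10BA", 15, "medium"),
    ("glibenclamide", "A10BB01", "A10BB", 1, "small"),
    ("glipizide", "A10BB07", "A10BB", 1, "small"),
    ("gliclazide", "A10BB09", "A10BB", 2, "small"),
    ("glimepiride", "A10BB12", "A10BB", 3, "small"),
    ("rosiglitazone", "A10BG02", "A10BG", 5, "medium"),
    ("pioglitazone", "A10BG03", "A10BG", 8, "medium"),
    ("sitagliptin", "A10BH01", "A10BH", 18, "large"),
    ("vildagliptin", "A10BH02", "A10BH", 9, "medium"),
    ("saxagliptin", "A10BH03", "A10BH", 9, "large"),
    ("alogliptin", "A10BH04", "A10BH", 5, "medium"),
    ("linagliptin", "A10BH05", "A10BH", 7, "medium"),
    ("gemigliptin", "A10BH06", "A10BH", 2, "small"),
    ("exenatide", "A10BJ01", "A10BJ", 11, "large"),
    ("liraglutide", "A10BJ02", "A10BJ", 15, "large"),
    ("lixisenatide", "A10BJ03", "A10BJ", 4, "medium"),
    ("dulaglutide", "A10BJ05", "A10BJ", 7, "large"),
    ("semaglutide", "A10BJ06", "A10BJ", 8, "large"),
    ("dapagliflozin", "A10BK01", "A10BK", 8, "large"),
    ("canagliflozin", "A10BK02", "A10BK", 7, "large"),
    ("empagliflozin", "A10BK03", "A10BK", 8, "large"),
    ("ertugliflozin", "A10BK04", "A10BK", 5, "medium"),
    ("nateglinide", "A10BX03", "A10BX", 2, "small"),
    ("taspoglutide", "A10BX90", "A10BX", 1, "small"),
]

# median extra enrollment above the 300 floor, and lognormal sigma
_SIZE_PARAMS = {"small": (150.0, 0.7), "medium": (500.0, 0.9), "large": (1200.0, 0.9)}


def build_standin_frame() -> pd.DataFrame:
    """Deterministically build the stand-in network as a DataFrame."""
    rng = np.random.default_rng(_BUILD_SEED)
    rows: list[dict] = []
    for name, drug_code, class_code, n_trials, size in _ALLOCATION:
        base, sigma = _SIZE_PARAMS[size]
        extras = base * np.exp(sigma * rng.standard_normal(n_trials))
        for k, extra in enumerate(extras, start=1):
            rows.append(
                {
                    "trial_id": f"{name.upper()[:4]}-{k:02d}",
                    "drug_code": drug_code,
                    "drug_name": name,
                    "class_code": class_code,
                    "enrollment_extra": float(extra),
                }
            )
    frame = pd.DataFrame(rows)
    assert len(frame) == TARGET_TRIALS

    # rescale the above-floor part so the total lands on the target exactly
    budget = TARGET_ENROLLMENT - MIN_ENROLLMENT * TARGET_TRIALS
    scale = budget / frame["enrollment_extra"].sum()
    enrollment = MIN_ENROLLMENT + np.floor(
        frame["enrollment_extra"].to_numpy() * scale
    ).astype(int)
    # rounding residual goes to the largest trial
    residual = TARGET_ENROLLMENT - int(enrollment.sum())
    enrollment[int(np.argmax(enrollment))] += residual
    frame = frame.drop(columns="enrollment_extra")
    frame["enrollment"] = enrollment

    assert int(frame["enrollment"].sum()) == TARGET_ENROLLMENT
    assert int(frame["enrollment"].min()) >= MIN_ENROLLMENT
    return frame[["trial_id", "drug_code", "drug_name", "class_code", "enrollment"]]
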