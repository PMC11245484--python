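"""Reference cohort metadata.

The published study this package emulates enrolled 12 physically fit students,
each examined twice (once acutely fatigued, once rested), with a Karolinska
Sleepiness Scale (KSS) self-report and a 2-minute Psychomotor Vigilance Test
(PVT) mean latency recorded before each session.  The per-subject scores are
reproduced here; they drive the simulator's KSS/PVT sampling distributions and
serve as the input for cohort-level summary statistics.
"""

from __future__ import annotations

import pandas as pd

# (subject, fatigue KSS, fatigue PVT ms, non-fatigue KSS, non-fatigue PVT ms)
_ROWS = [
    ("S01", 7, 553, 2, 365),
    ("S02", 8, 388, 3, 285),
    ("S03", 7, 404, 3, 324),
    ("S04", 7, 424, 3, 363),
    ("S05", 7, 447, 3, 365),
    ("S06", 7, 399, 3, 350),
    ("S07", 8, 386, 3, 346),
    ("S08", 7, 511, 3, 352),
    ("S09", 9, 532, 3, 393),
    ("S10", 8, 350, 2, 398),
    ("S11", 7, 646, 3, 362),
    ("S12", 7, 593, 3, 372),
]


def reference_cohort() -> pd.DataFrame:
    """Return the reference cohort in long form.

    One row per subject-session with columns ``subject_id``, ``condition``
    (``fatigue`` / ``non_fatigue``), ``kss`` and ``pvt_ms``.
    """
    records = []
    for sid, f_kss, f_pvt, n_kss, n_pvt in _ROWS:
        records.append((sid, "fatigue", f_kss, float(f_pvt)))
        records.append((sid, "non_fatigue", n_kss, float(n_pvt)))
    return pd.DataFrame(records, columns=["subject_id", "condition", "kss", "pvt_ms"])
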