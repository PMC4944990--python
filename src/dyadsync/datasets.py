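"""Bundled reference data: published per-dyad summaries from a classroom study.

A field study of pair-programming recorded ECG from 19 dyads (38
students) over ~90-minute sessions and published, per dyad, the summed
self-report items (MD, TD, Pe, Ef, Fr, Na — each member scoring 0–10,
so sums range 0–20) together with the within-dyad Pearson correlations
of HR, SDNN and rMSSD feature vectors at 60 s and 300 s window lengths.
That per-dyad summary table is reproduced here verbatim; it exercises
the compliance-averaging and regression stages on real published
numbers without needing the raw recordings.
"""

from __future__ import annotations

import io

import pandas as pd

_CLASSROOM_TSV = """\
sex	MD	TD	Pe	Ef	Fr	Na	r_hr_60	r_sdnn_60	r_rmssd_60	r_hr_300	r_sdnn_300	r_rmssd_300
MM	10	11	16	15	6	17	0.56	0.18	0.22	0.77	0.65	0.64
FF	10	12	10	14	11	13	0.19	0.38	-0.04	0.18	0.64	-0.02
MM	9	8	15	8	6	16	0.14	0.11	0.26	0.03	0.58	0.71
MF	11	11	12	15	14	17	0.63	0.38	0.18	0.80	0.56	0.23
MF	16	12	9	17	15	17	0.30	0.09	0.12	0.61	0.53	-0.22
MM	16	11	14	11	3	17	0.47	0.14	0.18	0.73	0.43	0.47
FF	13	11	9	15	17	16	-0.13	0.18	-0.05	-0.26	0.42	-0.24
MM	15	9	18	10	2	17	0.47	0.25	0.28	0.67	0.42	0.77
MF	10	10	9	10	7	15	0.32	0.04	0.14	0.37	0.41	0.06
FF	8	16	19	6	2	17	0.12	0.25	-0.18	-0.07	0.33	-0.54
MF	16	14	14	14	10	19	0.25	0.37	0.08	-0.09	0.33	0.18
MM	7	13	13	4	1	18	0.35	0.03	0.29	0.43	0.24	0.50
MF	14	11	10	16	11	12	0.01	0.28	0.17	-0.34	0.19	0.40
MF	12	11	15	17	10	20	0.11	0.22	0.15	0.02	0.15	0.50
MF	13	13	14	13	11	17	-0.20	0.09	-0.28	-0.42	0.15	-0.35
MM	13	14	18	11	4	19	-0.13	-0.01	-0.06	-0.60	0.00	-0.37
MF	11	11	9	10	9	10	0.37	0.16	0.31	0.67	-0.02	0.63
MF	13	14	12	15	8	17	0.34	0.13	-0.17	0.38	-0.11	-0.33
MF	12	16	6	18	14	15	0.31	-0.17	-0.16	0.35	-0.39	-0.27
"""


def load_classroom_study() -> pd.DataFrame:
    """Per-dyad published summary table (19 rows).

    Columns: dyad sex composition (MM/FF/MF), the six summed
    self-report items, and dyad correlations ``r_<feature>_<window>``
    for HR, SDNN, rMSSD at 60 s and 300 s windows (2-decimal precision
    as published).
    """
    df = pd.read_csv(io.StringIO(_CLASSROOM_TSV), sep="\t")
    df.index.name = "dyad_id"
    return df


def correlation_column(feature: str, window_length_s: int) -> str:
    """Column name for a (feature, window) correlation in the study table."""
    return f"r_{feature.lower()}_{int(window_length_s)}"
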