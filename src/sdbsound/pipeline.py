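"""In-memory pipeline helpers: recordings -> feature table -> evaluation.

These glue functions back both the CLI and the reproducibility scripts;
they operate on recordings already in memory (one at a time, so a whole
cohort never needs simultaneous residency beyond the audio itself).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from sdbsound import qtm as qtm_mod
from sdbsound.feature_extraction import FeatureConfig, extract_subject_features, feature_schema
from sdbsound.io_audio import AudioRecording


def subject_feature_row(
    rec: AudioRecording,
    config: FeatureConfig | None = None,
    qtm_frame_s: float = 1.0,
) -> tuple[dict[str, float], float]:
    """One subject's full feature vector (windowed stats + qTM) and APNEA occupancy."""
    config = config or FeatureConfig()
    vector = extract_subject_features(rec, config)
    q, levels = qtm_mod.extract_qtm(rec, frame_seconds=qtm_frame_s)
    vector.update(qtm_mod.qtm_features(q))
    return vector, levels.occupancy(qtm_mod.APNEA)


def cohort_feature_table(
    recordings: Mapping[str, AudioRecording] | Iterable[tuple[str, AudioRecording]],
    config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table (subjects x features) plus per-subject APNEA occupancy."""
    items = recordings.items() if isinstance(recordings, Mapping) else recordings
    rows, occs, index = [], [], []
    for sid, rec in items:
        vector, occ = subject_feature_row(rec, config)
        rows.append(vector)
        occs.append(occ)
        index.append(sid)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    assert list(table.columns) == feature_schema(config)
    assert not table.isna().any().any()
    return table, pd.Series(occs, index=table.index, name="apnea_occupancy")
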