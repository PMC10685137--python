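"""CSV readers/writers for the pipeline's tabular interchange formats.

All files are plain CSV with documented headers; genotype files use the
two-columns-per-locus dialect handled by :mod:`conflictsex.genotypes`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .flowers import FlowerRecord, census_states, flowers_to_frame, frame_to_flowers


def write_flowers(flowers: Sequence[FlowerRecord], path: str | Path) -> None:
    flowers_to_frame(flowers).to_csv(path, index=False)


def read_flowers(path: str | Path) -> list[FlowerRecord]:
    return frame_to_flowers(pd.read_csv(path, float_precision="round_trip"))


def write_censuses(flowers: Sequence[FlowerRecord], census_days: Sequence[int],
                   path: str | Path) -> None:
    census_states(flowers, census_days).to_csv(path, index=False)


def read_census_days(path: str | Path) -> list[int]:
    return sorted(pd.read_csv(path)["day"].unique().tolist())


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_sanitize(obj), indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _sanitize(obj):
    """Replace NaN/inf with None so the output is strict JSON."""
    import math

    import numpy as np
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        obj = float(obj)
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _jsonify(x):
    try:
        import numpy as np
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON-serializable: {type(x)}")
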