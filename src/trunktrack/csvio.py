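"""Long-format CSV trajectory dialect.

Columns ``frame,marker,x,y,z,occluded`` (header mandatory, mm units), with
a leading metadata comment line::

    # trunktrack rate=240 kind=gait subject=S01 sex=F

Occluded frames keep the ``occluded=1`` flag and empty coordinates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .trial import MarkerTrialSet


def write_csv_trial(trial: MarkerTrialSet, path) -> None:
    markers = list(trial.markers)
    n = trial.n_frames
    frames = np.repeat(np.arange(n), len(markers))
    marker_col = np.tile(markers, n)
    xyz = np.concatenate([
        np.stack([trial.positions[m][f] for m in markers])
        for f in range(n)
    ]) if n else np.empty((0, 3))
    occ = np.concatenate([
        [trial.occluded[m][f] for m in markers] for f in range(n)
    ]) if n else np.empty(0, bool)
    df = pd.DataFrame({
        "frame": frames, "marker": marker_col,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "occluded": occ.astype(int),
    })
    with open(path, "w", newline="") as fh:
        sex = trial.sex if trial.sex else "-"
        fh.write(f"# trunktrack rate={trial.rate:g} kind={trial.kind} "
                 f"subject={trial.subject} sex={sex}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_csv_trial(path) -> MarkerTrialSet:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# trunktrack"):
            raise FormatError("missing trunktrack metadata comment", line=1)
        meta = dict(tok.split("=", 1) for tok in first.split()[2:])
        df = pd.read_csv(fh)
    required = {"frame", "marker", "x", "y", "z", "occluded"}
    if not required <= set(df.columns):
        raise FormatError(f"CSV lacks columns {sorted(required - set(df.columns))}")
    try:
        rate = float(meta["rate"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad metadata: {exc}", line=1) from exc
    sex = meta.get("sex")
    sex = None if sex in (None, "-") else sex
    n = int(df["frame"].max()) + 1 if len(df) else 0
    positions, occluded = {}, {}
    for marker, sub in df.groupby("marker", sort=False):
        pos = np.full((n, 3), np.nan)
        occ = np.zeros(n, dtype=bool)
        idx = sub["frame"].to_numpy(dtype=int)
        pos[idx] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        occ[idx] = sub["occluded"].to_numpy(dtype=int).astype(bool)
        positions[str(marker)] = pos
        occluded[str(marker)] = occ
    return MarkerTrialSet(positions=positions, rate=rate,
                          kind=meta.get("kind", "dynamic"),
                          subject=meta.get("subject", "S00"), sex=sex,
                          occluded=occluded)
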