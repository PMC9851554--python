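"""Readers/writers for the deposited trial and results CSV dialects.

Trial files (one per trial, named ``FRI_<participant>_<lengthcode>.csv``)
carry four columns per sample: ``action`` (0 = no action, 1 = push
clockwise, 2 = push anti-clockwise), ``ang. velocity`` (rad/s), ``angle``
(rad in [0, 2*pi)) and ``utility`` (the trial-level score repeated on
every row).  In those files angle 0 is the UPRIGHT position, whereas the
internal convention puts 0 at the downward rest position; the reader and
writer translate between the two (shift by pi) according to an explicit
convention flag.

The results dialect has one row per trial with the verbatim headers
``Pend. Length``, ``Utility``, ``H(S)``, ``H(A|S)``, ``H(S'|A)``,
``I(A;S')``.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controllers import TrialRecord
from .dynamics import TWO_PI, Trajectory

TRIAL_COLUMNS = ["action", "ang. velocity", "angle", "utility"]
RESULTS_COLUMNS = ["Pend. Length", "Utility", "H(S)", "H(A|S)", "H(S'|A)", "I(A;S')"]

#: file action code -> internal action code.  File code 1 pushes clockwise,
#: which is the internal ``l`` action (code 0, control sign -u); file code 2
#: is anti-clockwise, internal ``r`` (code 2, +u); file code 0 is ``n``.
FILE_TO_INTERNAL_ACTION = {0: 1, 1: 0, 2: 2}
INTERNAL_TO_FILE_ACTION = {v: k for k, v in FILE_TO_INTERNAL_ACTION.items()}

_TRIAL_NAME = re.compile(r"FRI_(\d+)_(\d)\.csv$")


def parse_trial_filename(path: str | Path) -> tuple[int, float]:
    """Participant id and pendulum length from a ``FRI_p_l.csv`` name."""
    m = _TRIAL_NAME.search(Path(path).name)
    if not m:
        raise ValueError(f"not a trial filename: {Path(path).name}")
    participant = int(m.group(1))
    code = int(m.group(2))
    if not 2 <= code <= 9:
        raise ValueError(f"malformed length code {code} in {Path(path).name}")
    return participant, code / 10.0


def read_trial_csv(
    path: str | Path,
    angle_convention: str = "upright-zero",
    dt: float = 0.017,
) -> TrialRecord:
    """Parse one trial file into the internal (downward-zero) convention."""
    if angle_convention not in ("upright-zero", "downward-zero"):
        raise ValueError(f"unknown angle convention {angle_convention!r}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    codes = df["action"].to_numpy()
    bad = ~np.isin(codes, list(FILE_TO_INTERNAL_ACTION))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path.name}: invalid action code {codes[row]} at row {row}")
    utilities = df["utility"].to_numpy(dtype=float)
    if not np.allclose(utilities, utilities[0], atol=1e-9):
        row = int(np.flatnonzero(~np.isclose(utilities, utilities[0]))[0])
        raise ValueError(f"{path.name}: inconsistent utility column at row {row}")
    angles = df["angle"].to_numpy(dtype=float)
    if angle_convention == "upright-zero":
        angles = angles + math.pi
    angles = angles % TWO_PI
    actions = np.array([FILE_TO_INTERNAL_ACTION[int(c)] for c in codes], dtype=np.int64)
    traj = Trajectory(angles, df["ang. velocity"].to_numpy(dtype=float), actions, dt=dt)
    try:
        participant, length = parse_trial_filename(path)
    except ValueError:
        participant, length = None, float("nan")
    return TrialRecord(
        trajectory=traj,
        length=length,
        utility=float(utilities[0]),
        source="human",
        participant=participant,
    )


def write_trial_csv(
    record: TrialRecord,
    path: str | Path,
    angle_convention: str = "upright-zero",
) -> None:
    """Write a trial in the deposited dialect (round-trips with the reader)."""
    if angle_convention not in ("upright-zero", "downward-zero"):
        raise ValueError(f"unknown angle convention {angle_convention!r}")
    traj = record.trajectory
    if len(traj) == 0:
        raise ValueError("cannot write an empty trial")
    angles = traj.angles
    if angle_convention == "upright-zero":
        angles = (angles - math.pi) % TWO_PI
    df = pd.DataFrame(
        {
            "action": [INTERNAL_TO_FILE_ACTION[int(a)] for a in traj.actions],
            "ang. velocity": traj.speeds,
            "angle": angles,
            "utility": np.full(len(traj), record.utility),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trial_directory(
    directory: str | Path, angle_convention: str = "upright-zero"
) -> list[TrialRecord]:
    """All ``FRI_*_*.csv`` trials under a directory, sorted by name."""
    paths = sorted(Path(directory).glob("FRI_*_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial files (FRI_*_*.csv) under {directory}")
    return [read_trial_csv(p, angle_convention) for p in paths]


def write_results_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Metrics table in the results dialect, one row per trial."""
    out = pd.DataFrame(
        {
            "Pend. Length": table["length"],
            "Utility": table["utility"],
            "H(S)": table["H_S"],
            "H(A|S)": table["H_A_given_S"],
            "H(S'|A)": table["H_Sprime_given_A"],
            "I(A;S')": table["I_A_Sprime"],
        }
    )
    out.to_csv(path, index=False, float_format="%.9g")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a results-dialect CSV back into the internal column names."""
    df = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    return df.rename(
        columns={
            "Pend. Length": "length",
            "Utility": "utility",
            "H(S)": "H_S",
            "H(A|S)": "H_A_given_S",
            "H(S'|A)": "H_Sprime_given_A",
            "I(A;S')": "I_A_Sprime",
        }
    )


def load_config(path: str | Path) -> dict:
    """Load and minimally validate a YAML/JSON run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
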