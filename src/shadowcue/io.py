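"""File formats: trial-log CSV, PGM maps, session configuration.

Trial logs are plain CSV with a fixed, documented header (one row per
trial); luminance maps are stored as 8-bit PGM and depth maps as 16-bit PGM
in millimeters.  PGM files are written in the plain (ASCII, P2) variant so
every artifact stays text and diff-able.  Pixel coordinates everywhere are
0-based (col, row) with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .responder import ResponderParams
from .session import SessionConfig, TrialRecord

TRIAL_LOG_COLUMNS = [f.name for f in dc_fields(TrialRecord)]


class SchemaError(ValueError):
    pass


class MapFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trial logs


def write_trial_log(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV with the fixed column order.

    ``correct`` is blank for invalid responses; booleans are True/False.
    """
    df = pd.DataFrame([vars(r) for r in records], columns=TRIAL_LOG_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read a trial log; the inverse of :func:`write_trial_log`.

    Raises :class:`SchemaError` naming any missing/unknown column, and a
    ValueError with the line number for rows that do not parse.
    """
    df = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in TRIAL_LOG_COLUMNS]
    if unknown:
        raise SchemaError(f"trial log has unknown column(s): {', '.join(unknown)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                TrialRecord(
                    observer_id=row["observer_id"],
                    block_id=row["block_id"],
                    trial_index=int(row["trial_index"]),
                    t_probe=float(row["t_probe"]),
                    shadow_mode=row["shadow_mode"],
                    insertion_type=row["insertion_type"],
                    insertion_col=int(row["insertion_col"]),
                    insertion_row=int(row["insertion_row"]),
                    local_orientation=float(row["local_orientation"]),
                    congruent=_parse_bool(row["congruent"]),
                    response=row["response"],
                    correct=None if row["correct"] == "" else _parse_bool(row["correct"]),
                    consecutive_errors_after=int(row["consecutive_errors_after"]),
                    model_image_diff=float(row["model_image_diff"]) if row["model_image_diff"] != "" else float("nan"),
                    model_object_diff=float(row["model_object_diff"]) if row["model_object_diff"] != "" else float("nan"),
                    model_excluded=_parse_bool(row["model_excluded"]),
                )
            )
        except (ValueError, KeyError) as err:
            if isinstance(err, SchemaError):
                raise
            raise ValueError(f"trial log line {i + 2}: {err}") from err
    return records


def _parse_bool(s: str) -> bool:
    if s in ("True", "true", "1"):
        return True
    if s in ("False", "false", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def records_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=TRIAL_LOG_COLUMNS)


# ---------------------------------------------------------------------------
# Maps (plain PGM)


def write_map(grid: np.ndarray, path: str | Path, kind: str = "image") -> None:
    """Write a map as plain (P2) PGM.

    ``kind='image'``: luminance in [0, 1] quantized to 8 bits.
    ``kind='depth'``: meters stored as 16-bit millimeters.
    """
    grid = np.asarray(grid)
    if kind == "image":
        data = np.clip(np.round(grid * 255), 0, 255).astype(np.uint16)
        maxval = 255
    elif kind == "depth":
        data = np.clip(np.round(grid * 1000.0), 0, 65535).astype(np.uint16)
        maxval = 65535
    else:
        raise ValueError(f"unknown map kind {kind!r}")
    h, w = data.shape
    lines = [f"P2", f"{w} {h}", str(maxval)]
    lines += [" ".join(str(v) for v in row) for row in data]
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


def read_map(path: str | Path, kind: str = "image") -> np.ndarray:
    """Read a plain PGM map written by :func:`write_map`."""
    tokens = []
    text = Path(path).read_text(encoding="ascii")
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise MapFormatError("not a plain (P2) PGM file")
    try:
        w, h, maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
        vals = np.array([int(t) for t in tokens[4 : 4 + w * h]], dtype=float)
    except (IndexError, ValueError) as err:
        raise MapFormatError(f"malformed PGM: {err}") from err
    if vals.size != w * h:
        raise MapFormatError(
            f"dimension mismatch: header says {w}x{h}, found {vals.size} samples"
        )
    grid = vals.reshape(h, w)
    if kind == "image":
        return grid / 255.0
    if kind == "depth":
        return grid / 1000.0
    raise ValueError(f"unknown map kind {kind!r}")


# ---------------------------------------------------------------------------
# Session configuration (YAML)

_SESSION_KEYS = {"observers", "blocks_per_mode", "shadow_modes", "seed", "responders"}
_RESPONDER_KEYS = {f.name for f in dc_fields(ResponderParams)}


def read_session_config(path: str | Path) -> SessionConfig:
    """Parse a YAML session configuration; unknown keys are rejected.

    ``responders`` maps observer id -> shadow mode -> responder parameters
    (``w_drift`` as a [w_start, w_end, onset] list).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    unknown = set(raw) - _SESSION_KEYS
    if unknown:
        raise SchemaError(f"unknown session config key(s): {', '.join(sorted(unknown))}")
    responders = {}
    for obs, per_mode in (raw.get("responders") or {}).items():
        responders[obs] = {}
        for mode, params in per_mode.items():
            bad = set(params) - _RESPONDER_KEYS
            if bad:
                raise SchemaError(f"unknown responder key(s): {', '.join(sorted(bad))}")
            if "w_drift" in params and params["w_drift"] is not None:
                params = dict(params, w_drift=tuple(params["w_drift"]))
            responders[obs][mode] = ResponderParams(**params)
    return SessionConfig(
        observers=list(raw["observers"]),
        blocks_per_mode=int(raw.get("blocks_per_mode", 2)),
        shadow_modes=tuple(raw.get("shadow_modes", ("reliable", "absent", "unreliable"))),
        seed=int(raw.get("seed", 0)),
        responders=responders,
    )
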