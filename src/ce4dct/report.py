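"""Cohort-level aggregation and statistics.

Per-patient six-direction margin tables are summarized to per-direction mean
and sample SD (n-1), overall or by tumor group, rounded half-away-from-zero
to one decimal at the reporting layer only.  A reference cohort table with
twelve patients (six liver, six pancreatic) ships with the package as
``table2_margins.csv``.

Note on the group statistics: the source protocol applies a t-test even when
comparing medians; the paired t-test is implemented as stated.  Patient
covariates (age, performance status, ...) are deliberately excluded from
this module — the CSV schema simply tolerates extra columns so covariate
regressions can be run externally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structures import MarginVector

__all__ = [
    "DIRECTIONS",
    "GROUPS",
    "CohortMarginTable",
    "reference_margin_table",
    "load_margin_table",
    "summarize_margins",
    "paired_t_test",
    "round_half_away",
    "run_report",
]

DIRECTIONS = ("r", "l", "a", "p", "s", "i")
GROUPS = ("liver", "pancreatic")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class CohortMarginTable:
    """Per-patient six-direction margins with a tumor-group label each."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"patient_id", "group", *DIRECTIONS} - set(self.frame.columns)
        if missing:
            raise ValueError(f"margin table missing columns: {sorted(missing)}")
        bad = set(self.frame["group"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected {GROUPS}")
        vals = self.frame[list(DIRECTIONS)].to_numpy(float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("margins must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    def margins(self, patient_id: str) -> MarginVector:
        row = self.frame.loc[self.frame["patient_id"] == patient_id]
        if len(row) != 1:
            raise KeyError(f"patient {patient_id!r} not found (or duplicated)")
        return MarginVector(**{d: float(row.iloc[0][d]) for d in DIRECTIONS})


def reference_margin_table() -> CohortMarginTable:
    """The packaged twelve-patient reference cohort."""
    with resources.files("ce4dct.data").joinpath("table2_margins.csv").open() as fh:
        return CohortMarginTable(pd.read_csv(fh))


def load_margin_table(path: str | Path) -> CohortMarginTable:
    return CohortMarginTable(pd.read_csv(path))


def summarize_margins(
    table: CohortMarginTable, group: str | None = None
) -> dict[str, dict[str, float | None]]:
    """Per-direction mean and sample SD (n-1), to 0.1 mm.

    ``group`` filters to one tumor group; ``None`` summarizes the whole
    cohort.  With a single row the SD is reported as ``None``.
    """
    df = table.frame
    if group is not None:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
        df = df[df["group"] == group]
    if len(df) == 0:
        raise ValueError(f"no rows selected (group={group!r})")
    out: dict[str, dict[str, float | None]] = {}
    for d in DIRECTIONS:
        vals = df[d].to_numpy(float)
        sd = round_half_away(float(np.std(vals, ddof=1))) if len(vals) > 1 else None
        out[d] = {"mean": round_half_away(float(vals.mean())), "sd": sd,
                  "n": len(vals)}
    return out


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classic paired t on the differences; two-sided p with n-1 df.

    Identical inputs give (t=0, p=1); non-zero differences with zero variance
    are degenerate and rejected.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(xa)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = xa - ya
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 1.0
        raise ValueError("degenerate t-test: differences have zero variance")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def run_report(
    sections: Mapping[str, object] | None = None,
    *,
    seed: int | None = None,
    config: Mapping[str, object] | None = None,
    json_path: str | Path | None = None,
    markdown_path: str | Path | None = None,
    timestamp: str | None = None,
) -> dict:
    """Assemble stage outputs into one deterministic structured report.

    ``sections`` maps section names (e.g. ``"timing"``, ``"kinetics"``,
    ``"comparison"``, ``"margins"``) to dataclass instances, dicts, or
    anything with an ``as_dict`` method.  Output field ordering is
    deterministic; the ``timestamp`` field is the only non-reproducible one
    and may be pinned for byte-identical reports.
    """
    import dataclasses as dc
    import datetime

    from . import __version__

    def to_plain(obj):
        if obj is None:
            return None
        if hasattr(obj, "as_dict"):
            return to_plain(obj.as_dict())
        if dc.is_dataclass(obj) and not isinstance(obj, type):
            return to_plain(dc.asdict(obj))
        if isinstance(obj, Mapping):
            return {str(k): to_plain(obj[k]) for k in sorted(obj, key=str)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [to_plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    payload = {
        "provenance": {
            "tool": "ce4dct",
            "version": __version__,
            "seed": seed,
            "config": to_plain(dict(config) if config else {}),
            "timestamp": timestamp
            or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "sections": to_plain(dict(sections) if sections else {}),
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if markdown_path is not None:
        Path(markdown_path).write_text(_to_markdown(payload))
    return payload


def _to_markdown(payload: dict) -> str:
    lines = ["# ce4dct run report", ""]
    prov = payload["provenance"]
    lines += [f"- version: {prov['version']}", f"- seed: {prov['seed']}",
              f"- timestamp: {prov['timestamp']}", ""]
    for name in sorted(payload["sections"]):
        lines += [f"## {name}", "", "```json",
                  json.dumps(payload["sections"][name], indent=2, sort_keys=True),
                  "```", ""]
    return "\n".join(lines)
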