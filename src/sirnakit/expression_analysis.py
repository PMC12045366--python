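"""Plate-readout normalization, selectivity, hit calling, and IC50 fits.

Branched-DNA-style luminescence readouts are normalized per well as
target/housekeeping signal, then scaled to the mean control ratio of the
same probe, so a value of 1.0 means control-level expression.  Potency
is summarized by a four-parameter logistic (4PL) fit

    r(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

whose midpoint concentration is the IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CONTROL_GROUPS = {"NTC", "untreated"}

PLATE_COLUMNS = ["sample_id", "group", "probe", "target_signal",
                 "housekeeping_signal"]


@dataclass
class WellRecord:
    """One plate well: raw target and housekeeping luminescence."""

    sample_id: str
    group: str  # "treated:<compound>", "NTC", or "untreated"
    probe: str  # e.g. "total", "E1", "E2"
    target_signal: float
    housekeeping_signal: float
    concentration: Optional[float] = None  # molar

    def __post_init__(self) -> None:
        if self.target_signal < 0 or self.housekeeping_signal < 0:
            raise ValueError(f"negative signal in well {self.sample_id!r}")

    @property
    def compound(self) -> Optional[str]:
        if self.group.startswith("treated:"):
            return self.group.split(":", 1)[1]
        return None


@dataclass
class RelativeExpression:
    """Housekeeping-normalized expression as a fraction of control."""

    sample_id: str
    probe: str
    value: float
    group: str = ""
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("relative expression must be >= 0")


def read_plate_csv(path: str | Path) -> list[WellRecord]:
    """Read the plate CSV schema into well records.

    Columns: sample_id, group, probe, target_signal, housekeeping_signal
    and optionally concentration.  Schema violations report row numbers.
    """
    table = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    wells = []
    for idx, row in table.iterrows():
        try:
            conc = row.get("concentration")
            wells.append(
                WellRecord(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    probe=str(row["probe"]),
                    target_signal=float(row["target_signal"]),
                    housekeeping_signal=float(row["housekeeping_signal"]),
                    concentration=None if pd.isna(conc) else float(conc),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"plate CSV row {idx + 2}: {exc}") from exc
    return wells


def normalize(
    wells: Sequence[WellRecord],
    control_group: str = "NTC",
    control_stat: str = "mean",
) -> list[RelativeExpression]:
    """Normalize wells to the control-group mean ratio per probe.

    Wells with zero housekeeping signal are excluded (flagged via a
    ``UserWarning``-free skip; they simply do not appear in the output).
    Raises if any probe present in the data has no usable control well.
    """
    if control_stat not in {"mean", "median"}:
        raise ValueError("control_stat must be 'mean' or 'median'")
    usable = [w for w in wells if w.housekeeping_signal > 0]
    probes = {w.probe for w in usable}
    control_ratio: dict[str, float] = {}
    for probe in probes:
        ratios = [
            w.target_signal / w.housekeeping_signal
            for w in usable
            if w.probe == probe and w.group == control_group
        ]
        if not ratios:
            raise ValueError(
                f"no {control_group!r} control wells for probe {probe!r}"
            )
        control_ratio[probe] = (
            float(np.mean(ratios)) if control_stat == "mean"
            else float(np.median(ratios))
        )
    return [
        RelativeExpression(
            sample_id=w.sample_id,
            probe=w.probe,
            value=(w.target_signal / w.housekeeping_signal) / control_ratio[w.probe],
            group=w.group,
            concentration=w.concentration,
        )
        for w in usable
    ]


def selectivity_index(e1_remaining: float, e2_remaining: float) -> float:
    """Percent selectivity for silencing E1 over E2.

    S = 100 * max(0, 1 - e1/e2): 95% when E1 is reduced to 5% with E2
    intact, 0 when the compound silences E2 at least as strongly as E1.
    Invariant under common rescaling of both fractions.
    """
    if e1_remaining < 0 or e2_remaining < 0:
        raise ValueError("remaining fractions must be >= 0")
    if e2_remaining == 0:
        raise ValueError("selectivity undefined when E2 remaining is 0")
    return 100.0 * max(0.0, 1.0 - e1_remaining / e2_remaining)


@dataclass
class SelectivityResult:
    compound: str
    e1_remaining: float
    e2_remaining: float
    selectivity_pct: float


def screen_selectivity(
    expressions: Sequence[RelativeExpression],
) -> list[SelectivityResult]:
    """Per-compound E1-over-E2 selectivity from a normalized screen table."""
    frame = expressions_to_frame(expressions)
    treated = frame[frame["group"].str.startswith("treated:")]
    out = []
    for compound, grp in treated.groupby(
        treated["group"].str.split(":", n=1).str[1], sort=True
    ):
        means = grp.groupby("probe")["value"].mean()
        if "E1" not in means or "E2" not in means:
            continue
        out.append(
            SelectivityResult(
                compound=str(compound),
                e1_remaining=float(means["E1"]),
                e2_remaining=float(means["E2"]),
                selectivity_pct=selectivity_index(
                    float(means["E1"]), float(means["E2"])
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# 4PL dose-response


@dataclass
class DoseResponseFit:
    """4PL parameters; ``ic50`` is in the same molar units as the doses."""

    bottom: float
    top: float
    hill: float
    ic50: float
    converged: bool
    rss: float = math.nan
    n_points: int = 0


def four_pl(c: np.ndarray, bottom: float, top: float, hill: float,
            ic50: float) -> np.ndarray:
    """Four-parameter logistic response at concentrations ``c``."""
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _4pl_log(c, bottom, top, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(c) - log_ic50)))


def fit_4pl(
    concentrations: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Least-squares 4PL fit of relative expression vs concentration.

    The fit runs on log-concentration internally (ic50 parameterized as
    its logarithm) with initialization from the data range and the
    geometric-mean dose.  An unidentifiable or failed fit is returned
    with ``converged=False`` rather than raising.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses differ in length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")

    failed = DoseResponseFit(
        bottom=math.nan, top=math.nan, hill=math.nan, ic50=math.nan,
        converged=False, n_points=len(c),
    )
    if np.ptp(r) == 0:
        return failed
    # plateaus from the data range, midpoint from the geometric-mean dose;
    # ic50 confined to a wide window around the tested doses
    log_c = np.log(c)
    lower = (0.0, 0.0, 0.1, float(log_c.min() - np.log(1e4)))
    upper = (np.inf, np.inf, 10.0, float(log_c.max() + np.log(1e4)))
    p0 = np.clip(
        [float(r.min()), float(r.max()), 1.0, float(log_c.mean())],
        lower, upper,
    )
    try:
        popt, pcov = curve_fit(_4pl_log, c, r, p0=p0, bounds=(lower, upper),
                               maxfev=20000)
    except RuntimeError:
        return failed
    bottom, top, hill, log_ic50 = popt
    if not np.all(np.isfinite(popt)):
        return failed
    if bottom > top:  # equivalent reparameterization with hill negated
        bottom, top, hill = top, bottom, -hill
    ic50 = float(np.exp(log_ic50))
    if abs(top - bottom) < 1e-9 or not np.isfinite(pcov).all():
        return failed
    rss = float(np.sum((r - _4pl_log(c, *popt)) ** 2))
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill),
        ic50=ic50, converged=True, rss=rss, n_points=len(c),
    )


def hit_call(
    expressions: Sequence[RelativeExpression],
    threshold: float = 0.5,
    probe: Optional[str] = "total",
) -> list[str]:
    """Compounds whose mean remaining expression is <= threshold.

    The boundary is inclusive.  Returned sorted by ascending mean
    remaining expression (most potent first).
    """
    frame = expressions_to_frame(expressions)
    if frame.empty:
        return []
    treated = frame[frame["group"].str.startswith("treated:")]
    if probe is not None and (treated["probe"] == probe).any():
        treated = treated[treated["probe"] == probe]
    means = treated.groupby(
        treated["group"].str.split(":", n=1).str[1]
    )["value"].mean()
    hits = means[means <= threshold].sort_values()
    return [str(k) for k in hits.index]


def expressions_to_frame(
    expressions: Sequence[RelativeExpression],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "group": e.group,
                "probe": e.probe,
                "value": e.value,
                "concentration": e.concentration,
            }
            for e in expressions
        ]
    )
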