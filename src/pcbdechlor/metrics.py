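"""Quantitative dechlorination metrics from congener mole-percent time courses.

The central quantity is the mole-fraction-weighted mean chlorine count
of the mixture ("average chlorines per biphenyl").  Its decline over a
time window, multiplied by the mixture's total molar concentration,
gives the chloride-release rate in uM Cl- per day.  Positional
accounting splits the chlorine inventory into ortho/meta/para pools and
tracks the fraction of each pool removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .congeners import Congener, parse_congener

__all__ = [
    "CongenerProfile",
    "DechlorTimeCourse",
    "RateEstimate",
    "PositionalRemoval",
    "average_chlorine",
    "homolog_distribution",
    "total_molar_concentration",
    "dechlorination_rate",
    "fold_change",
    "positional_removal",
    "positional_rate_bias",
    "read_timecourses",
    "write_timecourses",
]

# GC-MS mole-percent tables routinely carry rounding drift; renormalize
# within this band, hard-error outside it.
_NORMALIZATION_BAND = 0.5

POSITION_CLASSES = ("ortho", "meta", "para")


@dataclass(frozen=True)
class CongenerProfile:
    """Mole-percent congener composition of one system at one timepoint.

    Entries are stored normalized to exactly 100; congeners absent from
    ``entries`` are exact zeros (below detection), not missing values.
    """

    system: str
    time_d: float
    entries: tuple  # ((Congener, mole_percent), ...) sorted by BZ number

    @classmethod
    def from_mapping(cls, system: str, time_d: float, entries) -> "CongenerProfile":
        acc: dict[Congener, float] = {}
        for key, value in dict(entries).items():
            c = parse_congener(key)
            acc[c] = acc.get(c, 0.0) + float(value)
        if not acc:
            raise ValueError(f"empty congener profile ({system!r}, t={time_d})")
        if any(v < 0 for v in acc.values()):
            raise ValueError("mole percentages must be non-negative")
        total = sum(acc.values())
        if abs(total - 100.0) > _NORMALIZATION_BAND:
            raise ValueError(
                f"mole percentages sum to {total:.3f}, outside 100 +/- "
                f"{_NORMALIZATION_BAND} ({system!r}, t={time_d})"
            )
        items = tuple(
            sorted(((c, v * 100.0 / total) for c, v in acc.items()),
                   key=lambda cv: (cv[0].n_cl, cv[0].bz or 0))
        )
        return cls(system=system, time_d=float(time_d), entries=items)

    def as_dict(self) -> dict:
        return dict(self.entries)

    @property
    def congeners(self) -> tuple:
        return tuple(c for c, _ in self.entries)

    def mole_percent(self, congener) -> float:
        c = parse_congener(congener)
        return self.as_dict().get(c, 0.0)

    def mean_molecular_weight(self) -> float:
        """Mole-fraction-weighted mean MW of the mixture, g/mol."""
        return sum(v / 100.0 * c.mw for c, v in self.entries)


@dataclass(frozen=True)
class DechlorTimeCourse:
    """Ordered congener profiles of one culture system.

    ``mass_conc_mg_l`` is the nominal mixture mass concentration (the
    study dosed Aroclor 1260 at 25 mg/L).
    """

    system: str
    profiles: tuple
    mass_conc_mg_l: float = 25.0

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("a time course needs at least one profile")
        times = [p.time_d for p in self.profiles]
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("profile times must be strictly increasing")
        if self.mass_conc_mg_l <= 0:
            raise ValueError("mass concentration must be positive")

    @property
    def times(self) -> tuple:
        return tuple(p.time_d for p in self.profiles)

    def at(self, time_d: float) -> CongenerProfile:
        for p in self.profiles:
            if np.isclose(p.time_d, time_d):
                return p
        raise KeyError(
            f"no profile at t={time_d} for {self.system!r}; have {self.times}"
        )


@dataclass(frozen=True)
class RateEstimate:
    """Chloride-release rate over a window, uM Cl- per day."""

    system: str
    t0: float
    t1: float
    delta_avg_cl: float
    molar_conc_um: float
    rate_um_cl_per_d: float


@dataclass(frozen=True)
class PositionalRemoval:
    """Per-position chlorine inventories and removal fractions.

    ``per_biphenyl_t0``/``per_biphenyl_t`` map each position class to
    chlorines per biphenyl; ``removal_fraction`` is 1 - N(t)/N(t0), or
    None (flagged not-applicable) when the class is absent at t0.
    """

    system: str
    t0: float
    t1: float
    per_biphenyl_t0: dict
    per_biphenyl_t: dict
    removal_fraction: dict


def average_chlorine(profile: CongenerProfile) -> float:
    """Average number of chlorine atoms per biphenyl of a profile."""
    return sum(v / 100.0 * c.n_cl for c, v in profile.entries)


def homolog_distribution(profile: CongenerProfile) -> pd.Series:
    """Mole percent by chlorination degree; 11 bins (0-10 Cl) summing to 100."""
    bins = np.zeros(11)
    for c, v in profile.entries:
        bins[c.n_cl] += v
    return pd.Series(bins, index=pd.RangeIndex(11, name="n_cl"), name="mole_percent")


def total_molar_concentration(tc: DechlorTimeCourse, at: float | None = None) -> float:
    """Total PCB molar concentration in uM, from the mixture's mean MW.

    Uses the profile at (or the latest one before) ``at``; defaults to
    the first profile.  25 mg/L at a mean MW of 372.6 g/mol is ~67.1 uM.
    """
    if at is None:
        profile = tc.profiles[0]
    else:
        earlier = [p for p in tc.profiles if p.time_d <= at + 1e-9]
        if not earlier:
            raise KeyError(f"no profile at or before t={at} for {tc.system!r}")
        profile = earlier[-1]
    return tc.mass_conc_mg_l / profile.mean_molecular_weight() * 1000.0


def dechlorination_rate(tc: DechlorTimeCourse, t0: float, t1: float) -> RateEstimate:
    """Chloride-release rate over [t0, t1] in uM Cl- per day.

    rate = (ClAvg(t0) - ClAvg(t1)) * molar concentration / (t1 - t0),
    with the molar concentration taken from the window-start profile.
    """
    if t1 <= t0:
        raise ValueError(f"window must be increasing, got t0={t0}, t1={t1}")
    p0, p1 = tc.at(t0), tc.at(t1)
    delta = average_chlorine(p0) - average_chlorine(p1)
    conc = total_molar_concentration(tc, at=t0)
    return RateEstimate(
        system=tc.system,
        t0=t0,
        t1=t1,
        delta_avg_cl=delta,
        molar_conc_um=conc,
        rate_um_cl_per_d=delta * conc / (t1 - t0),
    )


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio of two dechlorination rates (reference in the denominator)."""
    if rate_b <= 0:
        raise ValueError(f"reference rate must be positive, got {rate_b}")
    return rate_a / rate_b


def _positional_inventory(profile: CongenerProfile) -> dict:
    inv = {cls: 0.0 for cls in POSITION_CLASSES}
    for c, v in profile.entries:
        inv["ortho"] += v / 100.0 * c.n_ortho
        inv["meta"] += v / 100.0 * c.n_meta
        inv["para"] += v / 100.0 * c.n_para
    return inv


def positional_removal(tc: DechlorTimeCourse, t0: float, t1: float) -> PositionalRemoval:
    """Fraction of ortho/meta/para chlorines removed between t0 and t1."""
    inv0 = _positional_inventory(tc.at(t0))
    inv1 = _positional_inventory(tc.at(t1))
    removal = {}
    for cls in POSITION_CLASSES:
        if inv0[cls] > 0:
            removal[cls] = 1.0 - inv1[cls] / inv0[cls]
        else:
            removal[cls] = None  # class absent at t0: not applicable
    return PositionalRemoval(
        system=tc.system,
        t0=t0,
        t1=t1,
        per_biphenyl_t0=inv0,
        per_biphenyl_t=inv1,
        removal_fraction=removal,
    )


def positional_rate_bias(tc: DechlorTimeCourse, t0: float, t1: float) -> dict:
    """Per-chlorine initial removal rate by position class (d^-1).

    (N_pos(t0) - N_pos(t1)) / (N_pos(t0) * (t1 - t0)); a crude per-site
    rate useful for recovering the ordering of positional rate biases
    from simulated trajectories.  None where the class is absent at t0.
    """
    pr = positional_removal(tc, t0, t1)
    return {
        cls: (None if f is None else f / (t1 - t0))
        for cls, f in pr.removal_fraction.items()
    }


# -- I/O ----------------------------------------------------------------------
_LONG_COLUMNS = ["system", "time_d", "congener", "mole_percent"]


def read_timecourses(path, mass_conc_mg_l: float = 25.0) -> dict:
    """Read long-format (system, time_d, congener, mole_percent) CSV.

    The congener field accepts BZ numbers, ``PCB<n>`` labels, or
    structure strings.  Returns ``{system: DechlorTimeCourse}``.
    """
    df = pd.read_csv(path)
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"input CSV lacks column(s) {sorted(missing)}")
    out = {}
    for system, sys_df in df.groupby("system", sort=True):
        profiles = []
        for t, t_df in sys_df.groupby("time_d", sort=True):
            entries = {
                parse_congener(row.congener): float(row.mole_percent)
                for row in t_df.itertuples()
            }
            profiles.append(CongenerProfile.from_mapping(str(system), float(t), entries))
        out[str(system)] = DechlorTimeCourse(
            system=str(system), profiles=tuple(profiles), mass_conc_mg_l=mass_conc_mg_l
        )
    return out


def write_timecourses(timecourses, path) -> None:
    """Write time courses to the long-format CSV used by :func:`read_timecourses`."""
    if isinstance(timecourses, DechlorTimeCourse):
        timecourses = {timecourses.system: timecourses}
    rows = []
    for tc in timecourses.values():
        for p in tc.profiles:
            for c, v in p.entries:
                rows.append(
                    {"system": tc.system, "time_d": p.time_d,
                     "congener": c.bz, "mole_percent": v}
                )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def metrics_table(timecourses, windows) -> pd.DataFrame:
    """Tidy per-system, per-window metric table.

    ``windows`` is an iterable of (t0, t1) day pairs; systems lacking a
    profile at either end of a window are skipped with a warning.
    """
    rows = []
    for tc in timecourses.values():
        for t0, t1 in windows:
            try:
                rate = dechlorination_rate(tc, t0, t1)
                removal = positional_removal(tc, t0, t1)
            except KeyError as exc:
                warnings.warn(f"skipping window ({t0}, {t1}) for {tc.system!r}: {exc}")
                continue
            rows.append(
                {
                    "system": tc.system,
                    "t0": t0,
                    "t1": t1,
                    "avg_cl_t0": average_chlorine(tc.at(t0)),
                    "avg_cl_t1": average_chlorine(tc.at(t1)),
                    "delta_avg_cl": rate.delta_avg_cl,
                    "molar_conc_um": rate.molar_conc_um,
                    "rate_um_cl_per_d": rate.rate_um_cl_per_d,
                    **{
                        f"{cls}_removal_fraction": removal.removal_fraction[cls]
                        for cls in POSITION_CLASSES
                    },
                }
            )
    return pd.DataFrame(rows)


def metrics_json(timecourses, windows) -> str:
    """Machine-readable JSON rendering of :func:`metrics_table` (full precision)."""
    df = metrics_table(timecourses, windows)
    return json.dumps(df.to_dict(orient="records"), indent=2, allow_nan=True)
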