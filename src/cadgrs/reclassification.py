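"""Reclassification metrics: categorical NRI, category-free NRI, IDI.

These quantify the incremental value of adding a marker (here, genetic
risk score quartiles) to a baseline risk model.  The categorical net
reclassification improvement (NRI) works on a fixed risk-category grid
(< 25%, 25-50%, 50-75%, 75-100% by default): among events it is the net
percentage moving to a higher category, among nonevents the net
percentage moving lower, and the total is their sum.  The category-free
(continuous) NRI counts any increase/decrease of predicted risk.  The
integrated discrimination improvement (IDI) is the gain in discrimination
slope — mean predicted risk in events minus nonevents.

Standard errors are the usual asymptotic ones for net proportions of
movers (events and nonevents independent); percentile-bootstrap CIs are
available as an option for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_CUTPOINTS = (0.25, 0.50, 0.75)
Z975 = 1.959963984540054


def _categorize(pred: np.ndarray, cutpoints: tuple[float, ...]) -> np.ndarray:
    """0-based risk category; a value exactly at a cutpoint goes to the
    higher category."""
    return np.searchsorted(np.asarray(cutpoints), pred, side="right")


@dataclass(frozen=True)
class ReclassTable:
    """Old-category x new-category counts, split by event status."""

    events: np.ndarray  # (k x k) integer counts, rows = old, cols = new
    nonevents: np.ndarray
    cutpoints: tuple[float, ...]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevents.sum())

    def category_labels(self) -> list[str]:
        cuts = [0.0, *self.cutpoints, 1.0]
        return [f"{lo:.0%}-{hi:.0%}" for lo, hi in zip(cuts[:-1], cuts[1:])]

    def to_frame(self) -> pd.DataFrame:
        labels = self.category_labels()
        frames = []
        for group, counts in (("events", self.events),
                              ("nonevents", self.nonevents)):
            df = pd.DataFrame(counts, index=labels, columns=labels)
            df.insert(0, "group", group)
            df.insert(1, "old_category", labels)
            frames.append(df.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True)

    def cell_move_percentages(self) -> pd.DataFrame:
        """Per old-category percentage (of the whole group) moving up and
        down — the row-wise '% increase' / '% decrease' view of the
        table."""
        rows = []
        for group, counts, n in (("events", self.events, self.n_events),
                                 ("nonevents", self.nonevents, self.n_nonevents)):
            k = counts.shape[0]
            for old in range(k):
                up = counts[old, old + 1:].sum()
                down = counts[old, :old].sum()
                rows.append({"group": group, "old_category": old + 1,
                             "pct_up": 100.0 * up / n,
                             "pct_down": 100.0 * down / n})
        return pd.DataFrame(rows)


def build_reclass_table(
    pred_base,
    pred_new,
    labels,
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS,
) -> ReclassTable:
    """Cross-tabulate baseline-model vs new-model risk categories."""
    pb = np.asarray(pred_base, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(labels)
    if not (len(pb) == len(pn) == len(y)):
        raise ValueError("predictions and labels must have equal length")
    for name, p in (("pred_base", pb), ("pred_new", pn)):
        if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
            raise ValueError(f"{name} contains values outside [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    k = len(cutpoints) + 1
    old = _categorize(pb, cutpoints)
    new = _categorize(pn, cutpoints)
    tables = {}
    for grp, sel in (("events", y == 1), ("nonevents", y == 0)):
        counts = np.zeros((k, k), dtype=int)
        np.add.at(counts, (old[sel], new[sel]), 1)
        tables[grp] = counts
    return ReclassTable(tables["events"], tables["nonevents"], tuple(cutpoints))


@dataclass(frozen=True)
class NriResult:
    """Net reclassification improvement, as proportions in [-1, 1].

    ``event_component`` = P(up) - P(down) among events;
    ``nonevent_component`` = P(down) - P(up) among nonevents;
    ``total`` is their exact sum.  ``*_pct`` views scale by 100.
    """

    event_component: float
    nonevent_component: float
    se_events: float
    se_nonevents: float
    n_events: int
    n_nonevents: int
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    kind: str  # "categorical" | "category-free"
    degenerate: bool = False
    ci_override: tuple | None = None  # (lo_e, hi_e, lo_ne, hi_ne, lo_t, hi_t)

    @property
    def total(self) -> float:
        return self.event_component + self.nonevent_component

    @property
    def se_total(self) -> float:
        return float(np.sqrt(self.se_events ** 2 + self.se_nonevents ** 2))

    def _zp(self, est: float, se: float) -> tuple[float, float]:
        if se == 0:
            return 0.0, 1.0
        z = est / se
        return float(z), float(2 * norm.sf(abs(z)))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        comps = [
            ("events", self.event_component, self.se_events),
            ("nonevents", self.nonevent_component, self.se_nonevents),
            ("total", self.total, self.se_total),
        ]
        for i, (name, est, se) in enumerate(comps):
            z, p = self._zp(est, se)
            if self.ci_override is not None:
                lo, hi = self.ci_override[2 * i], self.ci_override[2 * i + 1]
            else:
                lo, hi = est - Z975 * se, est + Z975 * se
            rows.append({"component": name, "estimate": est, "se": se,
                         "ci_low": lo, "ci_high": hi, "z": z, "p": p,
                         "estimate_pct": 100 * est})
        return pd.DataFrame(rows)


def _nri_from_updown(up_e: int, down_e: int, n_e: int,
                     up_ne: int, down_ne: int, n_ne: int,
                     kind: str) -> NriResult:
    if n_e == 0 or n_ne == 0:
        raise ValueError("both events and nonevents must be present")
    pe_up, pe_dn = up_e / n_e, down_e / n_e
    pn_up, pn_dn = up_ne / n_ne, down_ne / n_ne
    se_e = np.sqrt(max((pe_up + pe_dn) / n_e - (pe_up - pe_dn) ** 2 / n_e, 0.0))
    se_ne = np.sqrt(max((pn_up + pn_dn) / n_ne - (pn_up - pn_dn) ** 2 / n_ne, 0.0))
    degenerate = (up_e + down_e + up_ne + down_ne) == 0
    return NriResult(pe_up - pe_dn, pn_dn - pn_up, float(se_e), float(se_ne),
                     n_e, n_ne, up_e, down_e, up_ne, down_ne, kind,
                     degenerate=degenerate)


def categorical_nri(table: ReclassTable) -> NriResult:
    """NRI over fixed risk categories, from a reclassification table."""
    def updown(counts: np.ndarray) -> tuple[int, int]:
        up = int(np.triu(counts, k=1).sum())
        down = int(np.tril(counts, k=-1).sum())
        return up, down

    up_e, down_e = updown(table.events)
    up_ne, down_ne = updown(table.nonevents)
    return _nri_from_updown(up_e, down_e, table.n_events,
                            up_ne, down_ne, table.n_nonevents, "categorical")


def cfnri(pred_base, pred_new, labels,
          ci: str = "asymptotic", n_boot: int = 2000,
          seed: int = 0) -> NriResult:
    """Category-free (continuous) NRI: any risk increase counts as an
    up-move, any decrease as a down-move, exact ties as neither."""
    pb = np.asarray(pred_base, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(labels)
    if not (len(pb) == len(pn) == len(y)):
        raise ValueError("predictions and labels must have equal length")
    d = pn - pb
    ev, ne = y == 1, y == 0
    res = _nri_from_updown(int((d[ev] > 0).sum()), int((d[ev] < 0).sum()),
                           int(ev.sum()),
                           int((d[ne] > 0).sum()), int((d[ne] < 0).sum()),
                           int(ne.sum()), "category-free")
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = np.empty((n_boot, 3))
        idx_e, idx_ne = np.flatnonzero(ev), np.flatnonzero(ne)
        for b in range(n_boot):
            se_ = rng.choice(idx_e, len(idx_e))
            sn_ = rng.choice(idx_ne, len(idx_ne))
            de, dn = d[se_], d[sn_]
            e_c = ((de > 0).mean() - (de < 0).mean())
            n_c = ((dn < 0).mean() - (dn > 0).mean())
            stats[b] = (e_c, n_c, e_c + n_c)
        lo = np.percentile(stats, 2.5, axis=0)
        hi = np.percentile(stats, 97.5, axis=0)
        res = NriResult(**{**res.__dict__,
                           "ci_override": (lo[0], hi[0], lo[1], hi[1],
                                           lo[2], hi[2])})
    return res


@dataclass(frozen=True)
class IdiResult:
    """Integrated discrimination improvement.

    ``slope_base``/``slope_new`` are each model's discrimination slope
    (mean predicted risk in events minus mean in nonevents); IDI is
    their difference, with SE from the per-subject improvements treated
    as a two-sample problem across events and nonevents.
    """

    slope_base: float
    slope_new: float
    se: float
    n_events: int
    n_nonevents: int
    ci_override: tuple[float, float] | None = None

    @property
    def idi(self) -> float:
        return self.slope_new - self.slope_base

    @property
    def ci(self) -> tuple[float, float]:
        if self.ci_override is not None:
            return self.ci_override
        return (self.idi - Z975 * self.se, self.idi + Z975 * self.se)

    @property
    def z(self) -> float:
        return self.idi / self.se if self.se > 0 else 0.0

    @property
    def p_value(self) -> float:
        return float(2 * norm.sf(abs(self.z))) if self.se > 0 else 1.0


def idi(pred_base, pred_new, labels,
        ci: str = "asymptotic", n_boot: int = 2000, seed: int = 0) -> IdiResult:
    """IDI = (slope_new - slope_base) with asymptotic (or bootstrap) CI."""
    pb = np.asarray(pred_base, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = np.asarray(labels)
    if not (len(pb) == len(pn) == len(y)):
        raise ValueError("predictions and labels must have equal length")
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both events and nonevents must be present")
    d = pn - pb
    slope_base = float(pb[ev].mean() - pb[ne].mean())
    slope_new = float(pn[ev].mean() - pn[ne].mean())
    se = float(np.sqrt(np.var(d[ev], ddof=1) / n_e
                       + np.var(d[ne], ddof=1) / n_ne))
    override = None
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = np.empty(n_boot)
        idx_e, idx_ne = np.flatnonzero(ev), np.flatnonzero(ne)
        for b in range(n_boot):
            de = d[rng.choice(idx_e, n_e)]
            dn = d[rng.choice(idx_ne, n_ne)]
            stats[b] = de.mean() - dn.mean()
        override = (float(np.percentile(stats, 2.5)),
                    float(np.percentile(stats, 97.5)))
    return IdiResult(slope_base, slope_new, se, n_e, n_ne, override)
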