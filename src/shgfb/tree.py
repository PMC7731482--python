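"""Relative-risk survival regression tree (one-step full-likelihood method).

The tree recursively partitions a cohort on covariate cutpoints chosen by
exhaustive search, scoring candidate splits with a Poisson-deviance criterion
under a proportional-hazards working model: the baseline cumulative hazard
``L(t)`` is estimated once at the root by the Nelson-Aalen estimator and held
fixed; each node is summarized by a constant relative risk

    theta = (sum of events in node) / (sum of L(t_i) over node patients)

and its deviance

    D = 2 * sum_i [ d_i * log(d_i / (theta * L(t_i))) - (d_i - theta * L(t_i)) ]

with the convention 0*log 0 = 0. A split's improvement is the parent deviance
minus the summed child deviances; growth stops on depth, node-size, event-count
or minimum-improvement controls. No pruning or cross-validation is performed
(the splitter is exposed so an ensemble or pruning pass could be layered on).

Covariates in the intended application are the S-ODX score plus six F/B
measures (bulk and tumor-stroma interface, each by three masking methods) on
the ln scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TreeControls",
    "RiskTree",
    "nelson_aalen",
    "node_deviance",
    "node_relative_risk",
    "best_split",
    "grow_tree",
    "assign_risk_groups",
    "render_tree",
]


@dataclass(frozen=True)
class TreeControls:
    """Stopping rules for tree growth.

    min_improvement is on the deviance (chi-square-like) scale; the default
    4.0 sits near the 95th percentile of chi-square(1), so splits on pure
    noise are usually rejected.
    """

    min_node_size: int = 10
    min_events: int = 3
    max_depth: int = 3
    min_improvement: float = 4.0

    def __post_init__(self) -> None:
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")


@dataclass
class RiskTree:
    """A node of the binary relative-risk tree.

    Internal nodes carry ``split_var``/``cutpoint`` (left child: value <
    cutpoint); leaves have ``split_var is None``. ``node_relative_risk`` is
    the node's event count divided by its expected count under the root
    baseline hazard.
    """

    node_patients: list
    n_events: int
    node_relative_risk: float
    deviance: float
    split_var: str | None = None
    cutpoint: float | None = None
    improvement: float = 0.0
    left: "RiskTree | None" = None
    right: "RiskTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self) -> list["RiskTree"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {
            "n": len(self.node_patients),
            "n_events": self.n_events,
            "relative_risk": self.node_relative_risk,
        }
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                cutpoint=self.cutpoint,
                improvement=self.improvement,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def nelson_aalen(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative-hazard estimator: (distinct event times, L)."""
    t = np.asarray(times, float)
    d = np.asarray(events).astype(int)
    event_times = np.unique(t[d == 1])
    increments = np.array(
        [((t == ti) & (d == 1)).sum() / (t >= ti).sum() for ti in event_times]
    )
    return event_times, np.cumsum(increments)


def cumulative_hazard_at(times, event_times, cumhaz) -> np.ndarray:
    """Evaluate the step-function cumulative hazard at each observed time."""
    idx = np.searchsorted(event_times, np.asarray(times, float), side="right")
    padded = np.concatenate([[0.0], cumhaz])
    return padded[idx]


def node_relative_risk(events, baseline_cumhaz) -> float:
    """theta = total events / total expected events under the root baseline."""
    d = np.asarray(events).astype(int)
    lam = np.asarray(baseline_cumhaz, float)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total baseline cumulative hazard in node")
    return float(d.sum() / total)


def node_deviance(events, baseline_cumhaz, risk: float | None = None) -> float:
    """One-step deviance of a node under constant relative risk.

    ``risk`` defaults to the node's own maximum-likelihood relative risk.
    """
    d = np.asarray(events).astype(float)
    lam = np.asarray(baseline_cumhaz, float)
    if lam.sum() <= 0:
        raise ValueError("zero total baseline cumulative hazard in node")
    theta = node_relative_risk(d, lam) if risk is None else float(risk)
    mu = theta * lam
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(d > 0, d * np.log(np.where(d > 0, d, 1.0) / np.where(mu > 0, mu, 1.0)), 0.0)
    return float(2.0 * (logterm - (d - mu)).sum())


def _child_deviances(d_sorted, lam_sorted):
    """Deviance of every prefix/suffix split of a covariate-sorted node.

    Exploits d in {0,1}: D = 2*[ D_ev*log(sum(L)/D_ev) - sum_ev log(L_i) ]
    when theta is the node MLE (the linear terms cancel), with D_ev*log(...)
    taken as 0 when the side has no events.
    """
    logl = np.where(d_sorted > 0, np.log(np.where(lam_sorted > 0, lam_sorted, 1.0)), 0.0)
    cum_d = np.cumsum(d_sorted)
    cum_l = np.cumsum(lam_sorted)
    cum_logl = np.cumsum(logl)
    tot_d, tot_l, tot_logl = cum_d[-1], cum_l[-1], cum_logl[-1]
    # prefix k = first k patients on the left (k = 1..n-1)
    dl, ll_, gl = cum_d[:-1], cum_l[:-1], cum_logl[:-1]
    dr, lr, gr = tot_d - dl, tot_l - ll_, tot_logl - gl
    # D = -2*[sum_ev log L_i + D_ev log(D_ev / sum L)], with 0*log0 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_left = -2.0 * (
            gl + np.where(dl > 0, dl * np.log(np.where(dl > 0, dl, 1.0) / ll_), 0.0)
        )
        dev_right = -2.0 * (
            gr + np.where(dr > 0, dr * np.log(np.where(dr > 0, dr, 1.0) / lr), 0.0)
        )
    return dev_left, dev_right, dl, dr


def best_split(
    data: pd.DataFrame,
    covariates: list[str],
    baseline_cumhaz: np.ndarray,
    controls: TreeControls,
) -> tuple[str, float, float] | None:
    """Exhaustive search for the deviance-optimal (covariate, cutpoint) split.

    Candidate cutpoints are midpoints between adjacent sorted unique covariate
    values; children must satisfy min_node_size and min_events. Returns
    (variable, cutpoint, improvement) or None when no admissible split exists.
    Ties are broken toward the earlier covariate in ``covariates`` and the
    smaller cutpoint, so the search is deterministic.
    """
    d = data["event"].to_numpy(int)
    lam = np.asarray(baseline_cumhaz, float)
    parent_dev = node_deviance(d, lam)
    best: tuple[str, float, float] | None = None
    for var in covariates:
        if var not in data.columns:
            raise ValueError(f"covariate {var!r} missing from data")
        x = data[var].to_numpy(float)
        order = np.argsort(x, kind="stable")
        xs, ds, ls = x[order], d[order], lam[order]
        if xs[0] == xs[-1]:
            continue
        dev_l, dev_r, ev_l, ev_r = _child_deviances(ds, ls)
        k = np.arange(1, xs.size)  # left size for prefix split at position k
        admissible = (
            (xs[1:] > xs[:-1])  # cutpoint only between distinct values
            & (k >= controls.min_node_size)
            & (xs.size - k >= controls.min_node_size)
            & (ev_l >= controls.min_events)
            & (ev_r >= controls.min_events)
        )
        if not admissible.any():
            continue
        imp = np.where(admissible, parent_dev - (dev_l + dev_r), -np.inf)
        j = int(np.argmax(imp))
        if imp[j] == -np.inf:
            continue
        cut = 0.5 * (xs[j] + xs[j + 1])  # left = first j+1 patients
        candidate = (var, float(cut), float(imp[j]))
        if best is None or candidate[2] > best[2] + 1e-12:
            best = candidate
    return best


def grow_tree(
    cohort: pd.DataFrame,
    covariates: list[str],
    controls: TreeControls | None = None,
    time_col: str = "mfs_time",
    event_col: str = "event",
    id_col: str = "patient_id",
) -> RiskTree:
    """Grow the relative-risk tree on a cohort table.

    The baseline cumulative hazard is estimated once from the full (root)
    sample and held fixed while splitting, per the one-step method. Growth is
    deterministic given the data.
    """
    controls = controls or TreeControls()
    if cohort.empty:
        raise ValueError("empty cohort")
    for c in covariates:
        if c not in cohort.columns:
            raise ValueError(f"covariate {c!r} missing from cohort")
    df = cohort.reset_index(drop=True).copy()
    df = df.rename(columns={time_col: "mfs_time", event_col: "event", id_col: "patient_id"})
    et, ch = nelson_aalen(df["mfs_time"], df["event"])
    df["_lambda"] = cumulative_hazard_at(df["mfs_time"], et, ch)

    def build(node_df: pd.DataFrame, depth: int) -> RiskTree:
        d = node_df["event"].to_numpy(int)
        lam = node_df["_lambda"].to_numpy(float)
        node = RiskTree(
            node_patients=list(node_df["patient_id"]),
            n_events=int(d.sum()),
            node_relative_risk=node_relative_risk(d, lam),
            deviance=node_deviance(d, lam),
        )
        if (
            depth >= controls.max_depth
            or len(node_df) < 2 * controls.min_node_size
            or d.sum() < 2 * controls.min_events
        ):
            return node
        found = best_split(node_df, covariates, lam, controls)
        if found is None or found[2] < controls.min_improvement:
            return node
        var, cut, imp = found
        node.split_var, node.cutpoint, node.improvement = var, cut, imp
        left_df = node_df[node_df[var] < cut]
        right_df = node_df[node_df[var] >= cut]
        node.left = build(left_df, depth + 1)
        node.right = build(right_df, depth + 1)
        return node

    return build(df, 0)


def assign_risk_groups(tree: RiskTree) -> pd.DataFrame:
    """Map every patient to a risk group, ranked 1 = highest relative risk."""
    leaves = sorted(tree.leaves(), key=lambda n: -n.node_relative_risk)
    rows = []
    for rank, leaf in enumerate(leaves, start=1):
        for pid in leaf.node_patients:
            rows.append(
                {
                    "patient_id": pid,
                    "risk_group": rank,
                    "relative_risk": leaf.node_relative_risk,
                }
            )
    return pd.DataFrame(rows)


def render_tree(tree: RiskTree, var_labels: dict[str, str] | None = None) -> str:
    """Plain-text diagram of the tree (split conditions and leaf risk summaries)."""
    var_labels = var_labels or {}
    lines: list[str] = []

    def walk(node: RiskTree, prefix: str, tag: str) -> None:
        n = len(node.node_patients)
        if node.is_leaf:
            lines.append(
                f"{prefix}{tag}leaf: n={n}, events={node.n_events}, "
                f"relative risk={node.node_relative_risk:.3g}"
            )
        else:
            name = var_labels.get(node.split_var, node.split_var)
            lines.append(
                f"{prefix}{tag}{name} < {node.cutpoint:.4g}  "
                f"(n={n}, improvement={node.improvement:.3g})"
            )
            walk(node.left, prefix + "  ", "yes: ")
            walk(node.right, prefix + "  ", "no:  ")

    walk(tree, "", "")
    return "\n".join(lines)
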