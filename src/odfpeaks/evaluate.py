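"""Peak-to-truth matching, angular deviation reports, and the factorial experiment.

Deviations are reported three ways per matched fiber: azimuth deviation and
elevation deviation in radians (both reduced under the antipodal equivalence
of orientations) and the antipodal arc in degrees.  A recovery is counted as
a success when the number of found peaks equals the number of true fibers
and every matched arc is within the matching threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hybrid import (
    HybridParams,
    Peak,
    PeakSet,
    canonical_direction,
    hybrid_find_peaks,
    objective_from,
)
from .phantom import (
    AcquisitionScheme,
    NoiseSpec,
    PhantomConfig,
    add_rician,
    simulate_signal,
)
from .recon import csa_odf, qbi_odf
from .sphere import SphereMesh, SphericalSamples, arc_angle, unit_to_sph

__all__ = [
    "DeviationReport",
    "match_peaks",
    "deviation_report",
    "grid_peaks",
    "run_experiment",
    "summarize_experiment",
    "plot_deviation_bars",
]


@dataclass(frozen=True)
class DeviationReport:
    """Angular errors of matched fibers plus detection counts."""

    azimuth_dev: np.ndarray    # rad, per matched pair
    elevation_dev: np.ndarray  # rad
    arc_dev: np.ndarray        # degrees, antipodal
    n_true: int
    n_found: int
    n_matched: int
    max_arc: float             # matching threshold used, degrees

    @property
    def success(self) -> bool:
        return (
            self.n_found == self.n_true
            and self.n_matched == self.n_true
            and bool(np.all(self.arc_dev <= self.max_arc))
        )

    @property
    def mean_arc(self) -> float:
        return float(self.arc_dev.mean()) if self.arc_dev.size else float("nan")

    @property
    def max_arc_dev(self) -> float:
        return float(self.arc_dev.max()) if self.arc_dev.size else float("nan")


def _as_directions(found) -> np.ndarray:
    if isinstance(found, PeakSet):
        return found.directions
    d = np.atleast_2d(np.asarray(found, dtype=float))
    return d.reshape(-1, 3) if d.size else np.zeros((0, 3))


def match_peaks(found, truth, max_arc: float = 20.0) -> list:
    """Optimal one-to-one matching between found and true orientations.

    Minimizes the total antipodal arc over all one-to-one assignments
    (Hungarian algorithm; exhaustive enumeration gives the same answer for
    the small instances used here) and drops pairs farther apart than
    ``max_arc`` degrees.  Returns ``[(i_found, j_truth, arc_deg), ...]``.
    """
    fd = _as_directions(found)
    td = np.atleast_2d(np.asarray(truth, dtype=float))
    if fd.shape[0] == 0 or td.shape[0] == 0:
        return []
    cost = arc_angle(fd[:, None, :], td[None, :, :], antipodal=True)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j), float(cost[i, j]))
        for i, j in zip(rows, cols)
        if cost[i, j] <= max_arc
    ]


def match_peaks_bruteforce(found, truth, max_arc: float = 20.0) -> list:
    """Exhaustive-enumeration matcher (independent oracle for small instances)."""
    fd = _as_directions(found)
    td = np.atleast_2d(np.asarray(truth, dtype=float))
    nf, nt = fd.shape[0], td.shape[0]
    if nf == 0 or nt == 0:
        return []
    cost = arc_angle(fd[:, None, :], td[None, :, :], antipodal=True)
    k = min(nf, nt)
    best, best_cost = None, np.inf
    for rows in itertools.permutations(range(nf), k):
        for cols in itertools.permutations(range(nt), k):
            total = sum(cost[i, j] for i, j in zip(rows, cols))
            if total < best_cost:
                best_cost, best = total, list(zip(rows, cols))
    return [
        (int(i), int(j), float(cost[i, j])) for i, j in best if cost[i, j] <= max_arc
    ]


def _angle_deviation(u_found: np.ndarray, u_true: np.ndarray):
    """Azimuth/elevation deviation (rad) under the antipodal equivalence.

    Both antipodal representatives of the found orientation are considered;
    the one closest to the truth in (azimuth, elevation) terms is reported.
    The azimuth difference is additionally reduced modulo pi.
    """
    tt, tp = unit_to_sph(u_true / np.linalg.norm(u_true))
    best = None
    for sign in (1.0, -1.0):
        ft, fp = unit_to_sph(sign * u_found / np.linalg.norm(u_found))
        dt = abs(ft - tt) % (2.0 * np.pi)
        dt = min(dt, 2.0 * np.pi - dt)
        dt = min(dt, np.pi - dt) if dt > np.pi / 2 else dt
        dp = abs(fp - tp)
        if best is None or dt + dp < best[0] + best[1]:
            best = (dt, dp)
    return best


def deviation_report(pairing, found, truth, max_arc: float = 20.0) -> DeviationReport:
    """Per-pair angular deviations and aggregate counts for a matching."""
    fd = _as_directions(found)
    td = np.atleast_2d(np.asarray(truth, dtype=float))
    azi, ele, arc = [], [], []
    for i, j, a in pairing:
        dt, dp = _angle_deviation(fd[i], td[j])
        azi.append(dt)
        ele.append(dp)
        arc.append(a)
    return DeviationReport(
        np.array(azi), np.array(ele), np.array(arc),
        n_true=td.shape[0], n_found=fd.shape[0], n_matched=len(arc),
        max_arc=max_arc,
    )


def grid_peaks(samples: SphericalSamples, relative_floor: float = 0.0,
               merge_angle: float = 10.0):
    """Brute-force peak oracle: strict 1-ring local maxima on the mesh.

    A vertex is a candidate when its value strictly exceeds every 1-ring
    neighbor and exceeds ``relative_floor`` times the global maximum.
    Candidates are antipodally deduplicated (descending value, ties to the
    lower vertex index).  Returns ``(PeakSet, plateau_flag)``; the flag marks
    ties between neighboring values (plateaus yield no strict maxima).
    """
    mesh = samples.mesh
    values = samples.values
    vmax = float(values.max())
    floor = relative_floor * vmax
    candidates = []
    plateau = False
    for i in range(mesh.n_vertices):
        nbr_vals = values[mesh.neighbors[i]]
        if np.any(nbr_vals == values[i]):
            plateau = True
        if values[i] > nbr_vals.max() and values[i] > floor:
            candidates.append(i)
    candidates.sort(key=lambda i: (-values[i], i))
    span = vmax - float(values.min())
    kept: list = []
    for i in candidates:
        u = canonical_direction(mesh.vertices[i])
        if all(arc_angle(u, k.direction, antipodal=True) >= merge_angle for k in kept):
            norm_val = (values[i] - values.min()) / span if span > 0 else 0.0
            kept.append(Peak(u, float(values[i]), float(norm_val)))
    return PeakSet(tuple(kept), merge_angle), plateau


def _reconstruct_objective(phantom: PhantomConfig, scheme: AcquisitionScheme,
                           recon: str, mesh: SphereMesh, snr, noise_seed: int):
    signal = simulate_signal(phantom, scheme)
    if snr is not None:
        signal = add_rician(signal, phantom.s0, NoiseSpec(snr, noise_seed))
    if recon == "analytic":
        if snr is not None:
            raise ValueError("the analytic ODF route is noiseless by definition")
        return objective_from(phantom, mode="analytic", mesh=mesh)
    if recon == "qbi":
        coeffs = qbi_odf(signal, scheme)
    elif recon == "csa":
        coeffs = csa_odf(signal, scheme)
    else:
        raise ValueError(f"unknown reconstruction {recon!r}")
    return objective_from(coeffs, mesh=mesh)


def run_experiment(phantoms, scheme: AcquisitionScheme, mesh: SphereMesh,
                   reconstructions=("analytic", "qbi", "csa"),
                   snr_levels=(None, 20.0), n_reps: int = 1, seed: int = 0,
                   params: HybridParams | None = None,
                   max_arc: float = 20.0) -> pd.DataFrame:
    """Factorial benchmark: phantoms x reconstructions x noise levels x repetitions.

    For every cell the hybrid optimizer extracts peaks from the chosen ODF
    representation and the result is matched against the phantom's true
    orientations.  Returns a tidy table with one row per matched fiber plus
    one summary row per unmatched case; deterministic given ``seed``.
    """
    params = params or HybridParams()
    rows = []
    base = np.random.SeedSequence(seed)
    for p_idx, phantom in enumerate(phantoms):
        truth = phantom.true_directions
        for recon in reconstructions:
            for snr in snr_levels:
                if recon == "analytic" and snr is not None:
                    continue
                for rep in range(n_reps):
                    child = base.spawn(1)[0]
                    run_seed = int(child.generate_state(1)[0] % (2**31 - 1))
                    obj = _reconstruct_objective(
                        phantom, scheme, recon, mesh, snr, run_seed
                    )
                    run_params = HybridParams(**{
                        **params.__dict__, "seed": run_seed
                    })
                    peaks = hybrid_find_peaks(obj, run_params)
                    pairing = match_peaks(peaks, truth, max_arc)
                    report = deviation_report(pairing, peaks, truth, max_arc)
                    common = dict(
                        phantom=p_idx, n_fibers=phantom.n_fibers, recon=recon,
                        snr=np.nan if snr is None else snr, rep=rep,
                        n_found=report.n_found, n_matched=report.n_matched,
                        success=report.success,
                    )
                    if report.n_matched:
                        for f, (azi, ele, arc) in enumerate(
                            zip(report.azimuth_dev, report.elevation_dev,
                                report.arc_dev)
                        ):
                            rows.append({**common, "fiber": f,
                                         "azimuth_dev_rad": azi,
                                         "elevation_dev_rad": ele,
                                         "arc_dev_deg": arc})
                    else:
                        rows.append({**common, "fiber": -1,
                                     "azimuth_dev_rad": np.nan,
                                     "elevation_dev_rad": np.nan,
                                     "arc_dev_deg": np.nan})
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/max angular deviations and success rate per phantom x condition."""
    keys = ["phantom", "recon", "snr"]
    grouped = table.groupby(keys, dropna=False)
    devs = grouped.agg(
        mean_azimuth_dev=("azimuth_dev_rad", "mean"),
        mean_elevation_dev=("elevation_dev_rad", "mean"),
        mean_arc_deg=("arc_dev_deg", "mean"),
        max_arc_deg=("arc_dev_deg", "max"),
    ).reset_index()
    # success is a per-run property: count each repetition once
    runs = table.drop_duplicates(subset=keys + ["rep"])
    rate = (
        runs.groupby(keys, dropna=False)["success"].mean().rename("success_rate")
    ).reset_index()
    return devs.merge(rate, on=keys)


def plot_deviation_bars(summary: pd.DataFrame, ax=None):
    """Grouped bar chart of mean azimuth/elevation deviations per condition.

    Takes the output of :func:`summarize_experiment`; one bar group per
    phantom x reconstruction x noise cell, azimuth and elevation side by
    side (radians).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(summary) + 2, 4))
    labels = [
        f"{int(r.phantom) + 1}f/{r.recon}" + ("" if pd.isna(r.snr) else f"/snr{r.snr:g}")
        for r in summary.itertuples()
    ]
    x = np.arange(len(summary))
    width = 0.38
    ax.bar(x - width / 2, summary["mean_azimuth_dev"], width, label="azimuth")
    ax.bar(x + width / 2, summary["mean_elevation_dev"], width, label="elevation")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("mean angular deviation (rad)")
    ax.legend()
    return ax
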