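"""Simulation benchmark: run all selectors over a grid and count per layer.

Replicates the simulation study design: for each (structure, δ) condition a
fresh dataset is generated per replicate (seed = base_seed + replicate, so
any subset of the grid reproduces identical data), every selector runs at
every level, and detections are counted per ground-truth layer. Detected
noise variables can be post-analyzed with a multivariate logistic regression
of the response on those columns only, reporting the likelihood-ratio model
p-value and the in-sample classification rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import fdr_select, stocsyo_select, ttest_pvalues
from .decomposition import FeatureTable, fit_biplot
from .selection import SelectionParams, select_features
from .simdata import (
    Layer,
    LayerStructure,
    SimulationDesign,
    Structure,
    generate_dataset,
)

__all__ = [
    "BenchmarkGrid",
    "BenchmarkResult",
    "METHODS",
    "count_by_layer",
    "noise_posthoc",
    "run_benchmark",
]

METHODS = ("bcr", "fdr_bh", "fdr_by", "stocsyo")

#: Table layers in reporting order; layer 1 pools strong and group-wise.
REPORT_LAYERS = ("layer1", "layer2", "layer3", "noise")

DEFAULT_LEVELS = (0.01, 0.03, 0.05, 0.07, 0.10, 0.15, 0.20)
DEFAULT_DELTAS = (0.0, 0.03, 0.05, 0.10)


@dataclass(frozen=True)
class BenchmarkGrid:
    """The benchmark's experimental grid."""

    structures: tuple[Structure, ...] = (Structure.THREE_LAYER,)
    deltas: tuple[float, ...] = (0.0,)
    levels: tuple[float, ...] = DEFAULT_LEVELS
    methods: tuple[str, ...] = METHODS
    n_reps: int = 100
    base_seed: int = 0
    n_samples: int = 200
    autoscale: bool = True
    with_posthoc: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if tuple(sorted(self.levels)) != tuple(self.levels):
            raise ValueError("levels must be sorted ascending")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class BenchmarkResult:
    """Long-format per-layer mean counts and optional noise post-analysis."""

    records: pd.DataFrame
    posthoc: pd.DataFrame
    n_failures: int = 0

    def mean_count(
        self, structure: str, delta: float, level: float, method: str, layer: str
    ) -> float:
        df = self.records
        row = df[
            (df.structure == structure)
            & np.isclose(df.delta, delta)
            & np.isclose(df.level, level)
            & (df.method == method)
            & (df.layer == layer)
        ]
        return float(row.mean_count.iloc[0])


def count_by_layer(
    selected: set[int] | np.ndarray, truth: LayerStructure
) -> dict[str, int]:
    """Count selected features per ground-truth layer (layer 1 pooled)."""
    if isinstance(selected, np.ndarray) and selected.dtype == bool:
        selected = set(np.flatnonzero(selected).tolist())
    counts = dict.fromkeys(REPORT_LAYERS, 0)
    pooled = {
        Layer.LAYER1_STRONG: "layer1",
        Layer.LAYER1_GROUP: "layer1",
        Layer.LAYER2: "layer2",
        Layer.LAYER3: "layer3",
        Layer.NOISE: "noise",
    }
    for j in selected:
        counts[pooled[truth.assignment[int(j)]]] += 1
    return counts


def noise_posthoc(
    table: FeatureTable, noise_selected: set[int] | list[int]
) -> tuple[float, float]:
    """Model p-value and accuracy of logistic regression on detected noise.

    Returns ``(nan, nan)`` when no noise variables were detected. When the
    number of selected columns approaches the sample count the fit falls
    back to a small ridge penalty for stability.
    """
    import statsmodels.api as sm

    idx = sorted(int(j) for j in noise_selected)
    if not idx:
        return (float("nan"), float("nan"))
    g0, g1 = table.group_values()
    y = (table.labels == g1).astype(float)
    design = sm.add_constant(table.X[:, idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            fit = model.fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False):
                raise np.linalg.LinAlgError
            llf, llnull = float(fit.llf), float(fit.llnull)
            prob = np.asarray(fit.predict(design))
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit_regularized(
                alpha=1e-4, L1_wt=0.0, disp=0, maxiter=500
            )
            prob = np.asarray(model.predict(fit.params, design))
            llf = float(model.loglike(fit.params))
            p1 = y.mean()
            llnull = float(
                y.sum() * np.log(p1) + (len(y) - y.sum()) * np.log(1 - p1)
            )
    from scipy import stats as sps

    lr = max(2.0 * (llf - llnull), 0.0)
    p_value = float(sps.chi2.sf(lr, df=len(idx)))
    accuracy = float(np.mean((prob >= 0.5) == (y == 1)))
    return (p_value, accuracy)


def _select_all_methods(
    table: FeatureTable,
    grid: BenchmarkGrid,
) -> dict[tuple[str, float], set[int]]:
    """Run every requested method at every level on one dataset."""
    out: dict[tuple[str, float], set[int]] = {}
    if "bcr" in grid.methods:
        model = fit_biplot(table, autoscale=grid.autoscale)
        cache: dict[int, float] = {}
        for level in grid.levels:
            params = SelectionParams(tau=level, autoscale=grid.autoscale)
            result = select_features(table=table, model=model, params=params,
                                     pvalue_cache=cache)
            out[("bcr", level)] = result.union_selected
    if "fdr_bh" in grid.methods or "fdr_by" in grid.methods:
        pvals = ttest_pvalues(table)
        for level in grid.levels:
            if "fdr_bh" in grid.methods:
                sel = fdr_select(pvals, level, "bh")
                out[("fdr_bh", level)] = set(np.flatnonzero(sel).tolist())
            if "fdr_by" in grid.methods:
                sel = fdr_select(pvals, level, "by")
                out[("fdr_by", level)] = set(np.flatnonzero(sel).tolist())
    if "stocsyo" in grid.methods:
        for level in grid.levels:
            sel = stocsyo_select(table, level, autoscale=grid.autoscale)
            out[("stocsyo", level)] = set(np.flatnonzero(sel).tolist())
    return out


def run_benchmark(grid: BenchmarkGrid) -> BenchmarkResult:
    """Execute the benchmark grid, averaging per-layer counts over replicates."""
    count_rows: list[dict] = []
    posthoc_rows: list[dict] = []
    n_failures = 0
    for structure in grid.structures:
        structure = Structure(structure)
        for delta in grid.deltas:
            # counts[(method, level, layer)] -> list over replicates
            acc: dict[tuple[str, float, str], list[float]] = {}
            ph: dict[tuple[str, float], list[tuple[float, float]]] = {}
            for rep in range(grid.n_reps):
                design = SimulationDesign(
                    n_samples=grid.n_samples,
                    structure=structure,
                    delta=delta,
                    seed=grid.base_seed + rep,
                )
                try:
                    table, truth = generate_dataset(design)
                    selections = _select_all_methods(table, grid)
                except Exception as err:  # pragma: no cover - defensive
                    warnings.warn(
                        f"replicate {rep} failed and was excluded: {err}",
                        stacklevel=2,
                    )
                    n_failures += 1
                    continue
                noise_idx = set(truth.indices(Layer.NOISE).tolist())
                for (method, level), selected in selections.items():
                    counts = count_by_layer(selected, truth)
                    for layer in REPORT_LAYERS:
                        acc.setdefault((method, level, layer), []).append(
                            counts[layer]
                        )
                    if grid.with_posthoc:
                        ph.setdefault((method, level), []).append(
                            noise_posthoc(table, selected & noise_idx)
                        )
            for (method, level, layer), values in acc.items():
                arr = np.asarray(values, dtype=float)
                count_rows.append(
                    {
                        "structure": structure.value,
                        "delta": delta,
                        "level": level,
                        "method": method,
                        "layer": layer,
                        "mean_count": arr.mean(),
                        "sd_count": arr.std(ddof=1) if arr.size > 1 else 0.0,
                        "n_reps": arr.size,
                    }
                )
            for (method, level), values in ph.items():
                ps = np.asarray([v[0] for v in values])
                rates = np.asarray([v[1] for v in values])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    posthoc_rows.append(
                        {
                            "structure": structure.value,
                            "delta": delta,
                            "level": level,
                            "method": method,
                            "model_p_value": float(np.nanmean(ps)),
                            "classification_rate": float(np.nanmean(rates)),
                            "n_applicable": int(np.isfinite(rates).sum()),
                        }
                    )
    records = pd.DataFrame(
        count_rows,
        columns=[
            "structure", "delta", "level", "method", "layer",
            "mean_count", "sd_count", "n_reps",
        ],
    )
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=[
            "structure", "delta", "level", "method",
            "model_p_value", "classification_rate", "n_applicable",
        ],
    )
    return BenchmarkResult(records=records, posthoc=posthoc, n_failures=n_failures)
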