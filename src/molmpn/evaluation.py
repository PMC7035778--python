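"""Cross-validation, hyperparameter grid search and the fingerprint baseline.

The splitting protocol is k-fold *stratified* cross-validation for a
continuous target: records are binned into 10 quantile bins of the target
and each bin is distributed proportionally over the folds, giving
80%/10%/10% train/validation/test partitions per fold (for k=10) with
every record landing in the test partition of exactly one fold.  Repeats
re-split with their own seeds.

The classical baseline is a random forest (500 trees) on hashed
circular-substructure fingerprints of fixed length 1024 (radius 2), the
conventional setup for structure-property regression.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestRegressor

from . import training as tr
from .chemgraph import DatasetRecord
from .encoder import param_rng

log = logging.getLogger(__name__)

FP_BITS = 1024
FP_RADIUS = 2
RF_TREES = 500


# ---------------------------------------------------------------------------
# splitting


@dataclasses.dataclass
class SplitPlan:
    """Per-fold train/validation/test index arrays."""

    folds: list          # per fold: dict with 'train'/'val'/'test' index arrays
    k: int
    seed: int


def _stratify_values(records: Sequence[DatasetRecord]) -> np.ndarray:
    # bin on the mean of the observed targets so multi-target tables with
    # partial coverage still stratify on something defined for every row
    return np.array([
        r.targets[r.mask].mean() if r.mask.any() else 0.0 for r in records
    ])


def stratified_split(records: Sequence[DatasetRecord], k: int = 10, seed: int = 0,
                     n_bins: int = 10) -> SplitPlan:
    """Quantile-stratified k-fold plan with ~(k-2)/k : 1/k : 1/k partitions.

    Fold f uses bin chunk f as test and chunk (f+1) mod k as validation;
    the rest trains.  Deterministic given the seed.
    """
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    values = _stratify_values(records)
    n_bins = min(n_bins, n)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, values, side="left")
    rng = param_rng(seed, "split")
    chunks: list[list[np.ndarray]] = [[] for _ in range(k)]
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        idx = rng.permutation(idx)
        # rotate which fold receives each bin's larger remainder chunk so
        # partition sizes stay balanced when bin sizes do not divide by k
        for j, part in enumerate(np.array_split(idx, k)):
            chunks[(j + int(b)) % k].append(part)
    chunk = [np.concatenate(c) for c in chunks]
    folds = []
    for f in range(k):
        test = np.sort(chunk[f])
        val = np.sort(chunk[(f + 1) % k])
        train = np.sort(np.concatenate([chunk[g] for g in range(k) if g not in (f, (f + 1) % k)]))
        folds.append({"train": train, "val": val, "test": test})
    return SplitPlan(folds=folds, k=k, seed=seed)


def check_no_leakage(records: Sequence[DatasetRecord], plan: SplitPlan) -> bool:
    """True iff no canonical structure appears in both train and test of any fold."""
    canon = [Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in records]
    for fold in plan.folds:
        train = {canon[i] for i in fold["train"]}
        test = {canon[i] for i in fold["test"]}
        if train & test:
            return False
    return True


# ---------------------------------------------------------------------------
# grid search


@dataclasses.dataclass
class GridSpace:
    """The standard hyperparameter lattice for these models."""

    activations: tuple = ("tanh", "elu", "leakyrelu", "relu", "prelu", "selu")
    depths: tuple = tuple(range(2, 7))                      # 2..6
    hidden_sizes: tuple = tuple(range(32, 513, 32))         # 32..512 step 32
    dropouts: tuple = tuple(np.round(np.arange(0.0, 0.401, 0.05), 2))
    ffn_layers: tuple = (1, 2, 3)

    def contains(self, point: dict) -> bool:
        return (point["activation"] in self.activations
                and point["depth"] in self.depths
                and point["hidden_size"] in self.hidden_sizes
                and round(float(point["dropout"]), 2) in {round(float(d), 2) for d in self.dropouts}
                and point["ffn_layers"] in self.ffn_layers)

    def enumerate(self):
        for a, d, h, p, l in itertools.product(
                self.activations, self.depths, self.hidden_sizes, self.dropouts, self.ffn_layers):
            yield {"activation": a, "depth": d, "hidden_size": h,
                   "dropout": float(p), "ffn_layers": l}

    def sample(self, n: int, seed: int = 0) -> list[dict]:
        """n distinct lattice points, uniformly without replacement."""
        rng = param_rng(seed, "gridspace")
        sizes = (len(self.activations), len(self.depths), len(self.hidden_sizes),
                 len(self.dropouts), len(self.ffn_layers))
        total = int(np.prod(sizes))
        flat = rng.choice(total, size=min(n, total), replace=False)
        points = []
        for ix in flat:
            coords = np.unravel_index(ix, sizes)
            points.append({
                "activation": self.activations[coords[0]],
                "depth": self.depths[coords[1]],
                "hidden_size": self.hidden_sizes[coords[2]],
                "dropout": float(self.dropouts[coords[3]]),
                "ffn_layers": self.ffn_layers[coords[4]],
            })
        return points


def grid_search(records: Sequence[DatasetRecord], space: GridSpace | None = None,
                budget: int = 10, seed: int = 0,
                evaluator: Callable[[dict], float] | None = None,
                config: tr.TrainConfig | None = None,
                attention: bool = True) -> tuple[dict, pd.DataFrame]:
    """Evaluate lattice points and return (best point, trial table).

    Points are ranked by validation RMSE.  The default evaluator trains a
    model on fold 0 of a stratified plan; pass *evaluator* to rank points
    by any other criterion (used heavily in tests).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or GridSpace()
    points = space.sample(budget, seed)
    if evaluator is None:
        plan = stratified_split(records, k=10, seed=seed)
        fold = plan.folds[0]
        train = [records[i] for i in fold["train"]]
        val = [records[i] for i in fold["val"]]
        base = config or tr.TrainConfig(epochs=10, seed=seed)

        def evaluator(point: dict) -> float:
            model = tr.MPNRegressor(
                hidden_size=point["hidden_size"], depth=point["depth"],
                ffn_layers=point["ffn_layers"], dropout=point["dropout"],
                activation=point["activation"], attention=attention,
                n_targets=len(train[0].targets), seed=seed)
            history = model.fit(train, val, base)
            return min(h["val"].rmse for h in history)

    trials = []
    for point in points:
        rmse = float(evaluator(dict(point)))
        trials.append({**point, "val_rmse": rmse})
        log.info("grid point %s -> val RMSE %.4f", point, rmse)
    table = pd.DataFrame(trials)
    best = table.loc[table["val_rmse"].idxmin()].to_dict()
    best = {k: best[k] for k in ("activation", "depth", "hidden_size", "dropout", "ffn_layers")}
    best["depth"] = int(best["depth"]); best["hidden_size"] = int(best["hidden_size"])
    best["ffn_layers"] = int(best["ffn_layers"]); best["dropout"] = float(best["dropout"])
    return best, table


# ---------------------------------------------------------------------------
# random forest baseline


def fingerprint(smiles: str, radius: int = FP_RADIUS, n_bits: int = FP_BITS) -> np.ndarray:
    """Hashed circular-substructure bit vector of fixed length 1024."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES not parseable: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.float64)


def rf_baseline(records: Sequence[DatasetRecord], split: SplitPlan, seed: int = 0,
                target_index: int = 0, n_trees: int = RF_TREES) -> list[tr.MetricsReport]:
    """Random-forest test metrics per fold (single target).

    The forest trains on the train+validation partitions (it needs no
    validation set) and is scored on the test partition; rows lacking the
    selected target are dropped.
    """
    fps, ok = {}, []
    for i, r in enumerate(records):
        if not r.mask[target_index]:
            continue
        try:
            fps[i] = fingerprint(r.smiles)
        except ValueError:
            log.warning("fingerprint failed for %r; record dropped", r.smiles)
            continue
        ok.append(i)
    ok = set(ok)
    y = np.array([r.targets[target_index] for r in records])
    reports = []
    for fold in split.folds:
        train_idx = [i for i in np.concatenate([fold["train"], fold["val"]]) if i in ok]
        test_idx = [i for i in fold["test"] if i in ok]
        X_train = np.stack([fps[i] for i in train_idx])
        X_test = np.stack([fps[i] for i in test_idx])
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X_train, y[train_idx])
        reports.append(tr.compute_metrics(rf.predict(X_test), y[test_idx]))
    return reports


# ---------------------------------------------------------------------------
# benchmark

MODEL_KINDS = ("rf", "mpn", "attn_mpn", "multi_mpn", "multi_attn_mpn")


def _net_fold_metrics(records, fold, *, attention: bool, multi: bool, seed: int,
                      target_index: int, config: tr.TrainConfig, **model_kwargs) -> tr.MetricsReport:
    train = [records[i] for i in fold["train"]]
    val = [records[i] for i in fold["val"]]
    test = [records[i] for i in fold["test"]]
    if not multi:
        def single(rs):
            return [DatasetRecord(r.smiles, [r.targets[target_index]], [r.mask[target_index]])
                    for r in rs if r.mask[target_index]]
        train, val, test = single(train), single(val), single(test)
    k = len(train[0].targets)
    model = tr.MPNRegressor(attention=attention, n_targets=k, seed=seed, **model_kwargs)
    model.fit(train, val, dataclasses.replace(config, seed=seed))
    pred = model.predict(test)
    y = np.stack([r.targets for r in test])
    m = np.stack([r.mask for r in test])
    if multi:
        col = target_index
        sel = m[:, col]
        return tr.compute_metrics(pred[sel, col], y[sel, col])
    return tr.compute_metrics(pred[:, 0], y[:, 0])


def run_benchmark(records: Sequence[DatasetRecord], models: Sequence[str] = ("rf", "mpn", "attn_mpn"),
                  k: int = 10, repeats: int = 3, seeds: Sequence[int] = (1, 2, 3),
                  target_index: int = 0, config: tr.TrainConfig | None = None,
                  **model_kwargs) -> pd.DataFrame:
    """Cross-validated comparison table (mean ± std per metric per model).

    ``attn_mpn`` is the self-attention model; ``mpn`` is the identical
    network with the attention stage replaced by plain average pooling;
    ``multi_*`` variants train on all target columns jointly and are scored
    on ``target_index``.  Each repeat re-splits with its own seed.
    """
    if repeats != len(seeds):
        raise ValueError("provide exactly one seed per repeat")
    unknown = set(models) - set(MODEL_KINDS)
    if unknown:
        raise ValueError(f"unknown model kind(s) {sorted(unknown)}; choose from {MODEL_KINDS}")
    config = config or tr.TrainConfig()
    rows = []
    for rep, seed in zip(range(repeats), seeds):
        plan = stratified_split(records, k=k, seed=seed)
        for name in models:
            if name == "rf":
                reports = rf_baseline(records, plan, seed=seed, target_index=target_index)
            else:
                reports = [
                    _net_fold_metrics(
                        records, fold,
                        attention="attn" in name, multi=name.startswith("multi"),
                        seed=seed, target_index=target_index, config=config, **model_kwargs)
                    for fold in plan.folds
                ]
            for f, rep_ in enumerate(reports):
                rows.append({"model": name, "repeat": rep, "fold": f, **rep_.as_dict()})
    raw = pd.DataFrame(rows)
    summary = raw.groupby("model", sort=False).agg(
        **{f"{m}_{s}": (m, s) for m in ("mae", "mse", "rmse", "r2", "pc") for s in ("mean", "std")}
    ).reset_index()
    summary.attrs["raw"] = raw
    return summary


def summary_to_markdown(summary: pd.DataFrame, metric: str = "rmse") -> str:
    """Compact model-comparison table ('mean ± std') for one metric."""
    lines = ["| Model | " + metric.upper() + " |", "|---|---|"]
    for _, row in summary.iterrows():
        lines.append(f"| {row['model']} | {row[f'{metric}_mean']:.3f} ± {row[f'{metric}_std']:.3f} |")
    return "\n".join(lines)
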