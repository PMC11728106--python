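"""Two-stage evaluation of imputation methods.

Stage 1 takes a complete (complete-case) matrix, injects missingness on
a grid of total-missing rates (alpha) and MNAR shares (beta) with
replicates, imputes with every requested method on the raw and/or log2
scale, and scores each run by NRMSE, ROC-AUC and confusion counts of
significance calls against the complete-data reference.

Stage 2 takes a matrix with natural (unlabelled) missingness, applies
the minimum-presence filter, imputes, and evaluates by true-positive
recovery, volcano counts at FDR/FC thresholds, and PCA group separation.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputers import METHODS, ImputerConfig, impute
from .matrix import LOG2, RAW, IntensityMatrix
from .metrics import confusion_counts, nrmse, reference_calls, roc_auc
from .missingness import MissingnessSpec, apply_missingness
from .stats import (call_significant, differential_analysis, filter_min_presence,
                    log2_transform, pca_group_separation)
from .synthetic import GroundTruth

RECORD_COLUMNS = ["method", "alpha", "beta", "replicate", "log_applied", "nrmse",
                  "auc", "tp", "fp", "tn", "fn", "runtime_seconds", "n_iterations",
                  "error"]


@dataclass
class GridSpec:
    """Stage-1 evaluation grid (defaults: 3 alphas x 5 betas x 10 replicates)."""

    alphas: tuple[float, ...] = (0.10, 0.25, 0.50)
    betas: tuple[float, ...] = (0.0, 0.20, 0.40, 0.80, 1.00)
    n_replicates: int = 10
    methods: tuple[str, ...] = METHODS
    log_options: tuple[str, ...] = (RAW, LOG2)
    fdr_threshold: float = 0.05
    fc_threshold: float = 2.0
    base_seed: int = 0
    mechanism: str = "hard_censor"
    min_observed_per_row: int = 1
    imputer_config: ImputerConfig = field(default_factory=ImputerConfig)

    @property
    def n_conditions(self) -> int:
        return len(self.alphas) * len(self.betas)

    @property
    def n_datasets(self) -> int:
        return self.n_conditions * self.n_replicates


@dataclass
class Stage1Result:
    records: pd.DataFrame
    n_conditions: int
    n_datasets: int


def child_seed(base_seed: int, *key: int) -> int:
    """Deterministic per-condition seed, decoupled across conditions."""
    return int(np.random.SeedSequence((base_seed, *key)).generate_state(1)[0] % (2**31))


def _group_pair(m: IntensityMatrix, group_pair: tuple[str, str] | None) -> tuple[str, str]:
    if group_pair is not None:
        return group_pair
    groups = m.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups for differential testing")
    return groups[0], groups[1]


def run_stage1_grid(complete: IntensityMatrix, spec: GridSpec,
                    group_pair: tuple[str, str] | None = None) -> Stage1Result:
    """Run the simulated-missingness benchmark grid on a complete matrix.

    One record per (method, alpha, beta, replicate, log option). Imputer
    failures are recorded with an error note and do not abort the run.
    """
    if not complete.is_complete:
        raise ValueError("stage 1 requires a complete matrix "
                         "(apply complete_case_subset first)")
    ga, gb = _group_pair(complete, group_pair)

    transforms: dict[str, IntensityMatrix] = {}
    references: dict[str, np.ndarray] = {}
    for log_opt in spec.log_options:
        mat = log2_transform(complete) if (log_opt == LOG2 and complete.scale == RAW) \
            else complete
        transforms[log_opt] = mat
        references[log_opt] = reference_calls(mat, ga, gb, spec.fdr_threshold)

    rows = []
    n_datasets = 0
    for ia, alpha in enumerate(spec.alphas):
        for ib, beta in enumerate(spec.betas):
            for rep in range(spec.n_replicates):
                seed = child_seed(spec.base_seed, ia, ib, rep)
                ds = apply_missingness(complete, MissingnessSpec(
                    alpha=alpha, beta=beta, mechanism=spec.mechanism,
                    min_observed_per_row=spec.min_observed_per_row, seed=seed))
                n_datasets += 1
                for il, log_opt in enumerate(spec.log_options):
                    complete_t = transforms[log_opt]
                    observed_t = ds.observed if log_opt != LOG2 \
                        else log2_transform(ds.observed)
                    ref = references[log_opt]
                    for mi, method in enumerate(spec.methods):
                        rows.append(_evaluate_one(
                            method, complete_t, observed_t, ds.mask, ref, ga, gb,
                            alpha, beta, rep, log_opt, spec,
                            imputer_seed=child_seed(seed, mi, il)))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return Stage1Result(records=records, n_conditions=spec.n_conditions,
                        n_datasets=n_datasets)


def _evaluate_one(method, complete_t, observed_t, mask, ref, ga, gb,
                  alpha, beta, rep, log_opt, spec, imputer_seed) -> dict:
    from dataclasses import replace

    base = dict(method=method, alpha=alpha, beta=beta, replicate=rep,
                log_applied=log_opt == LOG2, nrmse=np.nan, auc=np.nan,
                tp=np.nan, fp=np.nan, tn=np.nan, fn=np.nan,
                runtime_seconds=np.nan, n_iterations=np.nan, error="")
    cfg = replace(spec.imputer_config, seed=imputer_seed)
    try:
        result = impute(method, observed_t, cfg)
        base["runtime_seconds"] = result.runtime_seconds
        base["n_iterations"] = result.n_iterations
        base["nrmse"] = nrmse(complete_t, result.imputed, mask)
        diff = differential_analysis(result.imputed, ga, gb,
                                     fdr_threshold=spec.fdr_threshold)
        calls = diff.table["p_adjusted"].to_numpy() <= spec.fdr_threshold
        tp, fp, tn, fn = confusion_counts(ref, calls)
        base.update(tp=tp, fp=fp, tn=tn, fn=fn)
        _, auc = roc_auc(ref, 1.0 - diff.table["p_adjusted"].to_numpy())
        base["auc"] = auc
    except Exception as exc:  # non-fatal: one bad condition must not void the grid
        base["error"] = f"{type(exc).__name__}: {exc}"
    return base


def run_stage2_full(observed: IntensityMatrix,
                    methods: tuple[str, ...] = METHODS,
                    log_options: tuple[str, ...] = (RAW, LOG2),
                    min_fraction: float = 0.5,
                    ground_truth: GroundTruth | None = None,
                    fdr_threshold: float = 0.05,
                    fc_threshold: float = 2.0,
                    base_seed: int = 0,
                    group_pair: tuple[str, str] | None = None,
                    imputer_config: ImputerConfig | None = None) -> pd.DataFrame:
    """Evaluate imputation on a matrix with natural missingness.

    After the minimum-presence filter, each method x log option is
    imputed and scored by: number of true positives against the
    reference (ground-truth DE flags when available, otherwise the
    consensus of the evaluated methods' calls), volcano counts at the
    FDR and fold-change thresholds, and the PCA silhouette separation of
    the groups on the significant proteins.
    """
    ga, gb = _group_pair(observed, group_pair)
    filtered = filter_min_presence(observed, min_fraction)
    kept = [observed.protein_ids.index(pid) for pid in filtered.protein_ids]
    imputer_config = imputer_config or ImputerConfig()

    if ground_truth is not None:
        reference = ground_truth.de_flags[kept]
        reference_kind = "ground_truth"
    else:
        reference = None
        reference_kind = "consensus_majority"

    runs = []
    for il, log_opt in enumerate(log_options):
        mat = log2_transform(filtered) if (log_opt == LOG2 and filtered.scale == RAW) \
            else filtered
        for mi, method in enumerate(methods):
            from dataclasses import replace
            cfg = replace(imputer_config, seed=child_seed(base_seed, mi, il))
            entry = dict(method=method, log_applied=log_opt == LOG2,
                         n_proteins_tested=mat.n_proteins, error="")
            try:
                start = time.perf_counter()
                result = impute(method, mat, cfg)
                entry["runtime_seconds"] = time.perf_counter() - start
                diff = differential_analysis(result.imputed, ga, gb,
                                             fdr_threshold=fdr_threshold)
                p_adj = diff.table["p_adjusted"].to_numpy()
                fc = diff.table["log2_fc"].to_numpy()
                entry["_calls_fdr"] = call_significant(p_adj, fdr_threshold=fdr_threshold)
                entry["_calls_volcano"] = call_significant(
                    p_adj, fc, fdr_threshold, fc_threshold)
                entry["n_significant_fdr"] = int(entry["_calls_fdr"].sum())
                entry["n_significant_volcano"] = int(entry["_calls_volcano"].sum())
                sig_idx = np.flatnonzero(entry["_calls_volcano"])
                if sig_idx.size >= 2:
                    _, entry["pca_silhouette"] = pca_group_separation(result.imputed, sig_idx)
                else:
                    entry["pca_silhouette"] = np.nan
            except Exception as exc:
                entry["error"] = f"{type(exc).__name__}: {exc}"
                entry["_calls_fdr"] = None
            runs.append(entry)

    if reference is None:
        # consensus: proteins called significant (FDR) by a majority of runs
        stacks = [r["_calls_fdr"] for r in runs if r["_calls_fdr"] is not None]
        if not stacks:
            raise ValueError("all imputation runs failed; no consensus reference")
        votes = np.vstack(stacks).sum(axis=0)
        reference = votes > len(stacks) / 2

    rows = []
    for r in runs:
        row = {k: v for k, v in r.items() if not k.startswith("_")}
        if r["_calls_fdr"] is not None:
            tp, fp, tn, fn = confusion_counts(reference, r["_calls_fdr"])
            row.update(tp=tp, fp=fp, tn=tn, fn=fn)
        else:
            row.update(tp=np.nan, fp=np.nan, tn=np.nan, fn=np.nan)
        row["reference"] = reference_kind
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_report(records: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/median of NRMSE and AUC by (method, alpha, beta, log flag)."""
    if records.empty:
        raise ValueError("no records to summarize")
    keys = [k for k in ("method", "alpha", "beta", "log_applied") if k in records]
    grouped = records.groupby(keys, dropna=False)
    out = grouped.agg(
        nrmse_mean=("nrmse", "mean"),
        nrmse_sd=("nrmse", "std"),
        nrmse_median=("nrmse", "median"),
        auc_mean=("auc", "mean"),
        auc_sd=("auc", "std"),
        auc_median=("auc", "median"),
        n=("nrmse", "size"),
    ).reset_index()
    return out
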