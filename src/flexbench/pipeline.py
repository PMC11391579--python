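"""Per-protein and benchmark-level evaluation orchestration.

The evaluation of one protein follows a fixed order:

1. the experimental profile is computed on the whole chain — ensemble RMSF
   for NMR entries, B-factor conversion for X-ray entries;
2. the terminal truncation range is determined from that experimental
   profile alone (iterated passes for NMR, a single pass for X-ray) and is
   shared by every prediction method for that protein;
3. each method's predicted profiles are computed on the complete
   structures, replicate-averaged (normalize, mean, re-normalize), then
   restricted to the kept range;
4. both truncated profiles are normalized to unit maximum and compared
   with Pearson and Spearman correlations.

``evaluate_benchmark`` runs this over a manifest of proteins and emits the
summary tables: per-protein coefficients, group means, histograms,
cumulative distributions, skewness, two-way ANOVA, pairwise t-tests, the
signed significance matrix, and a chain-length table.  Proteins that fail
(degenerate truncation, constant profiles, mismatched residues) are
excluded and logged rather than aborting the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enm import DEFAULT_CUTOFF, DEFAULT_GAMMA, predict_profile
from .exceptions import FlexbenchError
from .geometry import ensemble_rmsf
from .metrics import (
    ProfilePair,
    cumulative_counts,
    histogram_counts,
    pearson,
    skewness,
    spearman,
)
from .profiles import (
    FluctProfile,
    TruncationRange,
    apply_truncation,
    average_replicates,
    normalize_profile,
    truncate_termini,
    xray_profile,
)
from .stats import pairwise_t, significance_matrix, two_way_anova
from .structio import read_calpha_ensemble
from .exceptions import UndefinedStatisticError, DesignError

__all__ = [
    "EvaluationConfig",
    "ProteinRecord",
    "BenchmarkResult",
    "evaluate_protein",
    "evaluate_benchmark",
]

ENM_METHOD = "enm"


@dataclass
class EvaluationConfig:
    """Settings for a benchmark evaluation run."""

    manifest_path: Path
    output_dir: Path
    data_dir: Path | None = None  # base for relative manifest paths
    chain: str | None = None
    include_enm: bool = False  # add the built-in elastic-network predictor
    enm_cutoff: float = DEFAULT_CUTOFF
    enm_gamma: float = DEFAULT_GAMMA
    truncate_threshold_sd: float = 1.0
    truncate_ddof: int = 1
    normalize_before_average: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.manifest_path = Path(self.manifest_path)
        self.output_dir = Path(self.output_dir)
        if self.data_dir is None:
            self.data_dir = self.manifest_path.parent
        self.data_dir = Path(self.data_dir)


@dataclass
class ProteinRecord:
    """Evaluation result for a single protein."""

    protein_id: str
    expt_method: str
    ss_class: str
    truncation: TruncationRange
    n_kept: int
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class BenchmarkResult:
    """Aggregated benchmark outputs."""

    table: pd.DataFrame  # tidy per-protein x method coefficients
    records: list[ProteinRecord]
    failures: list[tuple[str, str]]  # (protein_id, reason)
    output_dir: Path


def _read_profile_source(path: Path, chain: str | None, protein_id: str):
    return read_calpha_ensemble(
        path.read_text(), chain=chain, protein_id=protein_id
    )


def _experimental_profile(
    path: Path, expt_method: str, chain: str | None, protein_id: str
) -> tuple[FluctProfile, object]:
    """Whole-chain experimental profile plus the reference structure."""
    ensemble = _read_profile_source(path, chain, protein_id)
    if expt_method == "nmr":
        return ensemble_rmsf(ensemble, source="nmr"), ensemble.models[0]
    if expt_method == "xray":
        structure = ensemble.models[0]
        return xray_profile(structure), structure
    raise ValueError(f"unknown expt_method {expt_method!r}")


def evaluate_protein(
    protein_id: str,
    expt_method: str,
    ss_class: str,
    experimental_path: Path,
    predicted: dict[str, list[Path]],
    config: EvaluationConfig,
) -> ProteinRecord:
    """Run the per-protein pipeline and return its coefficients.

    ``predicted`` maps method name to the list of replicate ensemble files;
    with ``config.include_enm`` the built-in elastic-network predictor is
    added under the method name ``"enm"``, applied to the X-ray structure
    or NMR model 1.
    """
    expt_profile, reference = _experimental_profile(
        Path(experimental_path), expt_method, config.chain, protein_id
    )
    trange = truncate_termini(
        expt_profile,
        iterate=(expt_method == "nmr"),
        threshold_sd=config.truncate_threshold_sd,
        ddof=config.truncate_ddof,
    )
    expt_trunc = normalize_profile(apply_truncation(expt_profile, trange))

    methods: dict[str, FluctProfile] = {}
    for method, paths in predicted.items():
        reps = [
            ensemble_rmsf(
                _read_profile_source(Path(p), config.chain, protein_id),
                source="predicted",
            )
            for p in paths
        ]
        methods[method] = average_replicates(
            reps, normalize_first=config.normalize_before_average
        )
    if config.include_enm:
        methods[ENM_METHOD] = predict_profile(
            reference, cutoff=config.enm_cutoff, gamma=config.enm_gamma
        )

    record = ProteinRecord(
        protein_id=protein_id,
        expt_method=expt_method,
        ss_class=ss_class,
        truncation=trange,
        n_kept=len(expt_trunc),
    )
    for method, prof in methods.items():
        pred_trunc = normalize_profile(apply_truncation(prof, trange))
        pair = ProfilePair(predicted=pred_trunc, experimental=expt_trunc)
        record.coefficients[method] = (pearson(pair), spearman(pair))
    return record


def _load_manifest(config: EvaluationConfig) -> list[dict]:
    manifest = pd.read_csv(config.manifest_path)
    required = {
        "protein_id",
        "expt_method",
        "ss_class",
        "experimental_path",
        "method",
        "predicted_paths",
    }
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    proteins: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        pid = str(row["protein_id"])
        entry = proteins.setdefault(
            pid,
            {
                "protein_id": pid,
                "expt_method": row["expt_method"],
                "ss_class": row["ss_class"],
                "experimental_path": config.data_dir / row["experimental_path"],
                "predicted": {},
            },
        )
        paths = [
            config.data_dir / p
            for p in str(row["predicted_paths"]).split(";")
            if p and p != "nan"
        ]
        entry["predicted"][str(row["method"])] = paths
    return list(proteins.values())


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _group_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of both coefficients by method within every grouping margin."""
    frames = []
    margins = [
        ("expt_method", "ss_class"),
        ("expt_method", None),
        (None, "ss_class"),
        (None, None),
    ]
    for expt_col, class_col in margins:
        keys = ["method"] + [c for c in (expt_col, class_col) if c]
        g = table.groupby(keys, sort=True)
        agg = g.agg(
            r_p_mean=("r_p", "mean"),
            r_p_sd=("r_p", lambda v: v.std(ddof=1)),
            r_s_mean=("r_s", "mean"),
            r_s_sd=("r_s", lambda v: v.std(ddof=1)),
            n=("r_p", "size"),
        ).reset_index()
        if expt_col is None:
            agg.insert(1, "expt_method", "all")
        if class_col is None:
            agg.insert(2, "ss_class", "all")
        frames.append(agg[["method", "expt_method", "ss_class",
                           "r_p_mean", "r_p_sd", "r_s_mean", "r_s_sd", "n"]])
    return pd.concat(frames, ignore_index=True)


def evaluate_benchmark(config: EvaluationConfig) -> BenchmarkResult:
    """Evaluate every protein in the manifest and write all result tables."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    records: list[ProteinRecord] = []
    failures: list[tuple[str, str]] = []
    for entry in _load_manifest(config):
        try:
            records.append(
                evaluate_protein(
                    entry["protein_id"],
                    entry["expt_method"],
                    entry["ss_class"],
                    entry["experimental_path"],
                    entry["predicted"],
                    config,
                )
            )
        except FlexbenchError as exc:
            failures.append((entry["protein_id"], f"{type(exc).__name__}: {exc}"))

    rows = []
    for rec in records:
        for method, (rp, rs) in sorted(rec.coefficients.items()):
            rows.append(
                {
                    "protein_id": rec.protein_id,
                    "expt_method": rec.expt_method,
                    "ss_class": rec.ss_class,
                    "method": method,
                    "first_kept": rec.truncation.first_kept,
                    "last_kept": rec.truncation.last_kept,
                    "lnt": rec.truncation.lnt,
                    "lct": rec.truncation.lct,
                    "n_kept": rec.n_kept,
                    "r_p": rp,
                    "r_s": rs,
                }
            )
    table = pd.DataFrame(rows)
    result = BenchmarkResult(
        table=table, records=records, failures=failures, output_dir=out
    )
    if table.empty:
        raise FlexbenchError("no protein evaluated successfully")

    _fmt(table, out / "per_protein.csv")
    _fmt(_group_means(table), out / "group_means.csv")

    hist_rows, cum_rows, skew_rows = [], [], []
    for (expt, method), grp in table.groupby(["expt_method", "method"], sort=True):
        for response in ("r_p", "r_s"):
            values = grp[response].to_numpy(float)
            edges, counts = histogram_counts(values)
            for k in range(len(counts)):
                hist_rows.append(
                    {
                        "expt_method": expt,
                        "method": method,
                        "response": response,
                        "bin_left": edges[k],
                        "bin_right": edges[k + 1],
                        "count": counts[k],
                    }
                )
            xs, cs = cumulative_counts(values)
            for x, c in zip(xs, cs):
                cum_rows.append(
                    {
                        "expt_method": expt,
                        "method": method,
                        "response": response,
                        "x": x,
                        "count": c,
                    }
                )
            try:
                g1 = skewness(values)
                defined = True
            except (UndefinedStatisticError, ValueError):
                g1, defined = np.nan, False
            skew_rows.append(
                {
                    "expt_method": expt,
                    "method": method,
                    "response": response,
                    "skewness": g1,
                    "n": len(values),
                    "defined": defined,
                }
            )
    _fmt(pd.DataFrame(hist_rows), out / "histograms.csv")
    _fmt(pd.DataFrame(cum_rows), out / "cumulative.csv")
    _fmt(pd.DataFrame(skew_rows), out / "skewness.csv")

    anova_rows = []
    for expt in sorted(table["expt_method"].unique()):
        for response in ("r_p", "r_s"):
            try:
                res = two_way_anova(table, response=response, expt_method=expt)
            except DesignError as exc:
                failures.append((f"anova/{expt}/{response}", str(exc)))
                continue
            for factor, row in res.iterrows():
                anova_rows.append(
                    {
                        "expt_method": expt,
                        "response": response,
                        "factor": factor,
                        "sum_sq": row["sum_sq"],
                        "df": row["df"],
                        "F": row["F"],
                        "p": row["p"],
                    }
                )
    _fmt(pd.DataFrame(anova_rows), out / "anova.csv")

    methods = sorted(table["method"].unique())
    pair_rows, matrix_rows = [], []
    class_scopes = [None] + sorted(table["ss_class"].unique())
    for expt in sorted(table["expt_method"].unique()):
        for scope in class_scopes:
            try:
                mat = significance_matrix(
                    table,
                    methods=methods,
                    alpha=config.alpha,
                    expt_method=expt,
                    ss_class=scope,
                )
            except (UndefinedStatisticError, DesignError):
                continue
            for i, mi in enumerate(methods):
                for j, mj in enumerate(methods):
                    if i == j:
                        continue
                    response = "r_p" if i < j else "r_s"
                    matrix_rows.append(
                        {
                            "expt_method": expt,
                            "ss_class": scope or "all",
                            "row_method": mi,
                            "col_method": mj,
                            "response": response,
                            "label": mat.labels[i, j],
                            "p": mat.pvalues[i, j],
                        }
                    )
            for i, mi in enumerate(methods):
                for j, mj in enumerate(methods[i + 1 :], start=i + 1):
                    for response in ("r_p", "r_s"):
                        try:
                            t, df, p = pairwise_t(
                                table,
                                mi,
                                mj,
                                response=response,
                                expt_method=expt,
                                ss_class=scope,
                            )
                        except UndefinedStatisticError:
                            continue
                        pair_rows.append(
                            {
                                "expt_method": expt,
                                "ss_class": scope or "all",
                                "method_a": mi,
                                "method_b": mj,
                                "response": response,
                                "t": t,
                                "df": df,
                                "p": p,
                            }
                        )
    _fmt(pd.DataFrame(pair_rows), out / "pairs.csv")
    _fmt(pd.DataFrame(matrix_rows), out / "matrix.csv")

    _fmt(
        table[["protein_id", "expt_method", "method", "n_kept", "r_p", "r_s"]],
        out / "length_dependence.csv",
    )

    info = {
        "flexbench_version": __version__,
        "manifest": str(config.manifest_path),
        "n_proteins": int(table["protein_id"].nunique()),
        "methods": methods,
        "alpha": config.alpha,
        "seed": config.seed,
        "enm_cutoff": config.enm_cutoff,
        "enm_gamma": config.enm_gamma,
        "truncate_threshold_sd": config.truncate_threshold_sd,
        "truncate_ddof": config.truncate_ddof,
        "normalize_before_average": config.normalize_before_average,
        "failures": [list(f) for f in failures],
    }
    (out / "run_info.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return result
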