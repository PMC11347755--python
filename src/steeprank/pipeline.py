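"""End-to-end orchestration: dataset loading, the 8 steepness x rank-basis
meta-regression models with controls, restricted (linear-hierarchy) rerun,
interaction and steepness-only model sets, publication-bias tests, and
report output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dominance import (
    InteractionMatrix,
    davids_scores,
    linearity_test,
    ordinal_from_cardinal,
    read_sociomatrix_csv,
    steepness_from_scores,
)
from .effect_sizes import (
    BenefitTable,
    aggregate_measures,
    aggregate_steepness,
    fisher_z,
    pearson_r,
    signed_ordinal_r,
    z_variance,
)
from .elo_steepness import (
    EloConfig,
    McmcConfig,
    bayes_ds_steepness,
    bayes_elo_steepness,
    elo_rpt_steepness,
    fit_latent_strengths,
)
from .meta import (
    FULL_CONTROLS,
    DesignSpec,
    fit,
    lrt,
    phylo_signal,
    qe_test,
    small_study_test,
    time_lag_test,
)
from .phylo import correlation_matrix, grafen_branch_lengths, read_newick

log = logging.getLogger(__name__)

METHODS = ("NDS_Dij", "Elo_rpt", "Elo_Bayes", "DS_Bayes")
BASES = ("cardinal", "ordinal")

_STEEPNESS_COLS = {
    "NDS_Dij": "steepness_nds",
    "Elo_rpt": "steepness_elo_rpt",
    "Elo_Bayes": "steepness_elo_bayes",
    "DS_Bayes": "steepness_ds_bayes",
}


class DatasetError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Tunable settings, loadable from a YAML file with blocks
    elo:, bayes:, linearity:, meta:, simulate:."""

    seed: int = 0
    elo_n_randomizations: int = 1000
    elo_k: float = 100.0
    elo_start: float = 1000.0
    elo_scale: float = 400.0
    bayes_n_chains: int = 4
    bayes_n_iter: int = 1500
    bayes_burn_in: int = 1000
    bayes_proposal_sd: float = 0.3
    linearity_rand_unknown: int = 1000
    linearity_rand_null: int = 10000
    linearity_alpha: float = 0.05
    meta_n_starts: int = 3
    grafen_rho: float = 1.0
    simulate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        for block, prefix in (
            ("elo", "elo_"),
            ("bayes", "bayes_"),
            ("linearity", "linearity_"),
            ("meta", "meta_"),
        ):
            for key, val in (raw.get(block) or {}).items():
                kw[f"{prefix}{key}"] = val
        if "grafen_rho" in raw:
            kw["grafen_rho"] = float(raw["grafen_rho"])
        kw["simulate"] = raw.get("simulate") or {}
        return cls(**kw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_MODERATOR_COLS = (
    "benefit_type",
    "duration_months",
    "setting",
    "sex",
    "dispersal",
    "social_org",
    "origin",
)


@dataclasses.dataclass
class Dataset:
    table: pd.DataFrame
    matrices: dict[str, InteractionMatrix]
    benefits: dict[str, BenefitTable]
    tree: object
    A: object
    exclusions: list[str]
    path: Path | None = None


def load_dataset(path, grafen_rho: float = 1.0) -> Dataset:
    """Load and validate a dataset directory (see ``write_dataset``).

    Rows with n < 4 are excluded with a logged reason; a species missing
    from the tree is a hard error.
    """
    root = Path(path)
    csv = root / "dataset.csv"
    if not csv.exists():
        raise DatasetError(f"no dataset.csv under {root}")
    df = pd.read_csv(csv, dtype={"record_id": str, "group": str, "species": str})
    required = {"record_id", "group", "species", "n", *_MODERATOR_COLS}
    missing = sorted(required - set(df.columns))
    if missing:
        raise DatasetError(f"dataset.csv lacks column(s): {missing}")
    tree = read_newick(root / "tree.nwk")
    if not tree.is_ultrametric():
        tree = grafen_branch_lengths(tree, rho=grafen_rho)
    A = correlation_matrix(tree)
    tips = set(A.ids)
    bad_sp = sorted(set(df["species"]) - tips)
    if bad_sp:
        raise DatasetError(f"species absent from tree: {bad_sp}")

    exclusions: list[str] = []
    keep = []
    for _, row in df.iterrows():
        if int(row["n"]) < 4:
            msg = f"record {row['record_id']}: n = {int(row['n'])} < 4; excluded"
            log.info(msg)
            exclusions.append(msg)
        else:
            keep.append(row)
    df = pd.DataFrame(keep).reset_index(drop=True)
    if df.empty:
        raise DatasetError("all records excluded")

    matrices: dict[str, InteractionMatrix] = {}
    benefits: dict[str, BenefitTable] = {}
    for _, row in df.iterrows():
        mpath = row.get("matrix")
        if isinstance(mpath, str) and mpath:
            group = row["group"]
            if group not in matrices:
                matrices[group] = read_sociomatrix_csv(root / mpath)
        bpath = row.get("benefit")
        if isinstance(bpath, str) and bpath:
            bdf = pd.read_csv(root / bpath)
            if not {"individual", "benefit_value"} <= set(bdf.columns):
                raise DatasetError(f"benefit file {bpath} lacks required columns")
            benefits[row["record_id"]] = BenefitTable(
                ids=tuple(bdf["individual"].astype(str)),
                values=bdf["benefit_value"].to_numpy(dtype=float),
                benefit_type=str(row["benefit_type"]),
            )
    return Dataset(
        table=df,
        matrices=matrices,
        benefits=benefits,
        tree=tree,
        A=A,
        exclusions=exclusions,
        path=root,
    )


@dataclasses.dataclass
class GroupScores:
    steepness: dict[str, float]
    cardinal: dict[str, object]
    ordinal: dict[str, object]


def compute_group_scores(
    ds: Dataset, config: PipelineConfig
) -> dict[str, GroupScores]:
    """All four steepness measures and rank sets per group with a matrix."""
    out: dict[str, GroupScores] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(ds.matrices))
    for (group, m), seq in zip(sorted(ds.matrices.items()), seeds):
        s_elo, s_bayes, s_ds = seq.spawn(3)
        nds = davids_scores(m)
        elo_cfg = EloConfig(
            k=config.elo_k,
            start=config.elo_start,
            scale=config.elo_scale,
            n_randomizations=config.elo_n_randomizations,
            seed=s_elo,
        )
        rpt_res, rpt_ranks = elo_rpt_steepness(m, elo_cfg)
        mcmc = McmcConfig(
            n_chains=config.bayes_n_chains,
            n_iter=config.bayes_n_iter,
            burn_in=config.bayes_burn_in,
            proposal_sd=config.bayes_proposal_sd,
            seed=s_bayes,
        )
        draws = fit_latent_strengths(m, mcmc)
        eb_post, eb_ranks = bayes_elo_steepness(m, draws=draws)
        db_post, db_ranks = bayes_ds_steepness(
            m, dataclasses.replace(mcmc, seed=s_ds), n_draws=draws.shape[0]
        )
        cardinal = {
            "NDS_Dij": nds,
            "Elo_rpt": rpt_ranks,
            "Elo_Bayes": eb_ranks,
            "DS_Bayes": db_ranks,
        }
        out[group] = GroupScores(
            steepness={
                "NDS_Dij": steepness_from_scores(nds).estimate,
                "Elo_rpt": rpt_res.estimate,
                "Elo_Bayes": eb_post.mean,
                "DS_Bayes": db_post.mean,
            },
            cardinal=cardinal,
            ordinal={k: ordinal_from_cardinal(v) for k, v in cardinal.items()},
        )
    return out


def _aligned_scores(ranks, benefit: BenefitTable) -> np.ndarray:
    index = {x: i for i, x in enumerate(ranks.ids)}
    missing = [x for x in benefit.ids if x not in index]
    if missing:
        raise DatasetError(f"benefit ids not in matrix: {missing}")
    sel = [index[x] for x in benefit.ids]
    arr = ranks.rank if hasattr(ranks, "rank") else ranks.scores
    return np.asarray(arr, dtype=float)[sel]


def build_effect_frames(
    ds: Dataset, scores: dict[str, GroupScores]
) -> dict[tuple[str, str], pd.DataFrame]:
    """One record frame per (method, rank basis) combination.

    Rows sharing a record_id (several benefit measures of the same thing)
    are aggregated by averaging r; several matrices per group are not
    distinguished here — their steepness average must be precomputed.
    Rows without raw data use the precomputed ``r`` and per-method
    steepness columns.
    """
    frames: dict[tuple[str, str], list[dict]] = {
        (m, b): [] for m in METHODS for b in BASES
    }
    for rec_id, rows in ds.table.groupby("record_id", sort=False):
        first = rows.iloc[0]
        group = first["group"]
        n = int(first["n"])
        meta_cols = {
            "record_id": rec_id,
            "group": group,
            "species": first["species"],
            "benefit_category": (
                "direct"
                if first["benefit_type"] in ("fecundity", "infant_survival")
                else "indirect"
            ),
            "duration_months": float(first["duration_months"]),
            "setting": first["setting"],
            "sex": first["sex"],
            "dispersal": first["dispersal"],
            "social_org": first["social_org"],
            "origin": first["origin"],
            "pub_year": (
                float(first["pub_year"])
                if str(first.get("pub_year", "")) not in ("", "nan")
                else np.nan
            ),
            "n": n,
        }
        has_raw = group in scores and rec_id in ds.benefits
        for method in METHODS:
            for basis in BASES:
                if has_raw:
                    gs = scores[group]
                    rs = []
                    for _, row in rows.iterrows():
                        benefit = ds.benefits[rec_id]
                        if basis == "cardinal":
                            rs.append(
                                pearson_r(
                                    benefit.values,
                                    _aligned_scores(gs.cardinal[method], benefit),
                                )
                            )
                        else:
                            ranks = gs.ordinal[method]
                            idx = {x: i for i, x in enumerate(ranks.ids)}
                            sel = [idx[x] for x in benefit.ids]
                            sub = dataclasses.replace(
                                ranks,
                                ids=tuple(benefit.ids),
                                rank=np.asarray(ranks.rank)[sel],
                            )
                            rs.append(signed_ordinal_r(benefit.values, sub))
                    r = aggregate_measures(rs)
                    steep = gs.steepness[method]
                else:
                    if "r" not in rows.columns or pd.isna(first.get("r")):
                        raise DatasetError(
                            f"record {rec_id}: no raw data and no precomputed r"
                        )
                    r = aggregate_measures([float(x) for x in rows["r"]])
                    col = _STEEPNESS_COLS[method]
                    if col not in rows.columns or pd.isna(first.get(col)):
                        raise DatasetError(
                            f"record {rec_id}: missing precomputed column {col}"
                        )
                    steep = aggregate_steepness([float(x) for x in rows[col]])
                frames[(method, basis)].append(
                    {
                        **meta_cols,
                        "r": r,
                        "z_r": fisher_z(r),
                        "v": z_variance(n),
                        "steepness": steep,
                        "method": method,
                        "rank_basis": basis,
                    }
                )
    return {key: pd.DataFrame(rows) for key, rows in frames.items()}


@dataclasses.dataclass
class AnalysisReport:
    lrt_table: pd.DataFrame
    bias_table: pd.DataFrame | None
    sections: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        out = {
            "lrt_table": self.lrt_table.to_dict(orient="records"),
            "bias_table": (
                self.bias_table.to_dict(orient="records")
                if self.bias_table is not None
                else None
            ),
            "sections": _jsonable(self.sections),
            "provenance": self.provenance,
        }
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _model_row(
    frame: pd.DataFrame,
    A,
    method: str,
    basis: str,
    full_spec: DesignSpec,
    control_spec: DesignSpec,
    n_starts: int,
    with_signal: bool = True,
) -> dict:
    full = fit(frame, full_spec, A, method="ML", n_starts=n_starts)
    control = fit(frame, control_spec, A, method="ML", n_starts=n_starts)
    test = lrt(full, control)
    row = {
        "method": method,
        "rank_basis": basis,
        "k": full.k,
        "df_full": full.df_model,
        "df_control": control.df_model,
        "lrt_chi2": test.chi2,
        "lrt_df": test.df,
        "lrt_p": test.p,
        "qm": full.qm,
        "qm_df": full.qm_df,
        "qm_p": full.qm_p,
    }
    qe, qe_df, qe_p = qe_test(frame, full_spec)
    row.update(qe=qe, qe_df=qe_df, qe_p=qe_p)
    if with_signal:
        sig = phylo_signal(frame, full_spec, A, n_starts=n_starts)
        row.update(lambda_hat=sig.lambda_hat, lambda_chi2=sig.chi2, lambda_p=sig.p)
    return row


def _eight_model_loop(
    frames: dict, A, full_spec: DesignSpec, control_spec: DesignSpec, n_starts: int
) -> pd.DataFrame:
    rows = []
    for method in METHODS:
        for basis in BASES:
            rows.append(
                _model_row(
                    frames[(method, basis)],
                    A,
                    method,
                    basis,
                    full_spec,
                    control_spec,
                    n_starts,
                )
            )
    return pd.DataFrame(rows)


def _provenance(ds: Dataset, config: PipelineConfig, extra: dict | None = None) -> dict:
    prov = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_records": int(ds.table["record_id"].nunique()),
        "exclusions": ds.exclusions,
    }
    if extra:
        prov.update(extra)
    return prov


def run_bias_tests(frames: dict, A, n_starts: int) -> pd.DataFrame:
    """Small-study and time-lag meta-regressions on the published subset,
    one per effect-size variant (cardinal basis of each method)."""
    rows = []
    for method in METHODS:
        frame = frames[(method, "cardinal")]
        pub = frame[frame["origin"] == "published"].copy()
        if pub.empty:
            raise DatasetError("no published records for bias tests")
        z_ss, p_ss = small_study_test(pub, A, n_starts=n_starts)
        z_tl, p_tl = time_lag_test(pub, A, n_starts=n_starts)
        rows.append(
            {
                "method": method,
                "small_study_z": z_ss,
                "small_study_p": p_ss,
                "time_lag_z": z_tl,
                "time_lag_p": p_tl,
                "k_published": len(pub),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(
    ds: Dataset,
    config: PipelineConfig | None = None,
    scores: dict[str, GroupScores] | None = None,
    with_bias: bool = True,
) -> AnalysisReport:
    """The paper-style main analysis: 8 full-vs-control model comparisons
    (4 steepness measures x {cardinal, ordinal} response bases), each with
    Q_M, Q_E and phylogenetic signal, plus publication-bias tests."""
    config = config or PipelineConfig()
    if scores is None:
        scores = compute_group_scores(ds, config)
    frames = build_effect_frames(ds, scores)
    table = _eight_model_loop(
        frames, ds.A, DesignSpec.full(), DesignSpec.control(), config.meta_n_starts
    )
    bias = run_bias_tests(frames, ds.A, config.meta_n_starts) if with_bias else None
    return AnalysisReport(
        lrt_table=table,
        bias_table=bias,
        sections={},
        provenance=_provenance(ds, config),
    )


def linearity_filter(
    ds: Dataset, config: PipelineConfig
) -> tuple[Dataset, dict[str, float]]:
    """Drop records from groups without a significantly linear hierarchy."""
    seeds = np.random.SeedSequence((config.seed, 1)).spawn(len(ds.matrices))
    pvals: dict[str, float] = {}
    for (group, m), seq in zip(sorted(ds.matrices.items()), seeds):
        res = linearity_test(
            m,
            rand_unknown=config.linearity_rand_unknown,
            rand_null=config.linearity_rand_null,
            seed=seq,
        )
        pvals[group] = res.p_value
    if "linear" in ds.table.columns:
        flagged = {
            str(row["group"]): bool(row["linear"])
            for _, row in ds.table.iterrows()
            if str(row["group"]) not in ds.matrices and not pd.isna(row.get("linear"))
        }
    else:
        flagged = {}
    keep_groups = {g for g, p in pvals.items() if p < config.linearity_alpha}
    keep_groups |= {g for g, ok in flagged.items() if ok}
    table = ds.table[ds.table["group"].isin(keep_groups)].reset_index(drop=True)
    if table.empty:
        raise DatasetError("no groups pass the linearity filter")
    removed = sorted(set(ds.table["group"]) - keep_groups)
    sub = Dataset(
        table=table,
        matrices={g: m for g, m in ds.matrices.items() if g in keep_groups},
        benefits={
            r: b for r, b in ds.benefits.items() if r in set(table["record_id"])
        },
        tree=ds.tree,
        A=ds.A,
        exclusions=ds.exclusions
        + [f"group {g}: hierarchy not significantly linear; removed" for g in removed],
        path=ds.path,
    )
    return sub, pvals


def run_restricted(
    ds: Dataset,
    config: PipelineConfig | None = None,
    scores: dict[str, GroupScores] | None = None,
) -> AnalysisReport:
    """Rerun of the main analysis on groups with significantly linear
    hierarchies only."""
    config = config or PipelineConfig()
    sub, pvals = linearity_filter(ds, config)
    if scores is None:
        scores = compute_group_scores(sub, config)
    else:
        scores = {g: s for g, s in scores.items() if g in sub.matrices}
    frames = build_effect_frames(sub, scores)
    table = _eight_model_loop(
        frames, ds.A, DesignSpec.full(), DesignSpec.control(), config.meta_n_starts
    )
    n_kept = int(sub.table["record_id"].nunique())
    return AnalysisReport(
        lrt_table=table,
        bias_table=None,
        sections={"linearity_p": pvals},
        provenance=_provenance(
            sub,
            config,
            {"restricted": True, "n_retained_records": n_kept},
        ),
    )


_INTERACTION_FACTORS = ("dispersal", "setting", "sex")


def run_interaction_models(
    ds: Dataset,
    config: PipelineConfig | None = None,
    factor: str = "dispersal",
    scores: dict[str, GroupScores] | None = None,
) -> pd.DataFrame:
    """Steepness x factor interaction models.

    The full model adds steepness, the factor's centered dummies and their
    products; the control drops all three, so the LRT df is 1 + 2 x
    (levels - 1)."""
    if factor not in _INTERACTION_FACTORS:
        raise ValueError(f"factor must be one of {_INTERACTION_FACTORS}")
    config = config or PipelineConfig()
    if scores is None:
        scores = compute_group_scores(ds, config)
    frames = build_effect_frames(ds, scores)
    for frame in frames.values():
        if frame[factor].nunique() < 2:
            raise DatasetError(f"factor {factor!r} has a single observed level")
    controls_wo = tuple(c for c in FULL_CONTROLS if c != factor)
    full_spec = DesignSpec(
        predictors=("steepness",) + FULL_CONTROLS, interaction=factor
    )
    control_spec = DesignSpec(predictors=controls_wo)
    rows = []
    for method in METHODS:
        for basis in BASES:
            rows.append(
                _model_row(
                    frames[(method, basis)],
                    ds.A,
                    method,
                    basis,
                    full_spec,
                    control_spec,
                    config.meta_n_starts,
                    with_signal=False,
                )
            )
    out = pd.DataFrame(rows)
    out.insert(0, "interaction_factor", factor)
    return out


def run_simpler_models(
    ds: Dataset,
    config: PipelineConfig | None = None,
    scores: dict[str, GroupScores] | None = None,
    restricted: bool = False,
) -> pd.DataFrame:
    """Steepness-only full models against intercept-only controls."""
    config = config or PipelineConfig()
    if restricted:
        ds, _ = linearity_filter(ds, config)
        scores = None
    if scores is None:
        scores = compute_group_scores(ds, config)
    frames = build_effect_frames(ds, scores)
    rows = []
    for method in METHODS:
        for basis in BASES:
            rows.append(
                _model_row(
                    frames[(method, basis)],
                    ds.A,
                    method,
                    basis,
                    DesignSpec(predictors=("steepness",)),
                    DesignSpec.intercept_only(),
                    config.meta_n_starts,
                    with_signal=False,
                )
            )
    out = pd.DataFrame(rows)
    out.insert(0, "dataset", "restricted" if restricted else "full")
    return out


def write_report(report: AnalysisReport, outdir, formats=("csv", "json", "txt")) -> list[Path]:
    """Write the report as CSV, JSON and/or human-readable text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = outdir / "lrt_table.csv"
        report.lrt_table.to_csv(p, index=False)
        written.append(p)
        if report.bias_table is not None:
            p = outdir / "bias_table.csv"
            report.bias_table.to_csv(p, index=False)
            written.append(p)
    if "json" in formats:
        p = outdir / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(report.to_json_dict(), fh, indent=1)
        written.append(p)
    if "txt" in formats:
        p = outdir / "report.txt"
        lines = [
            "steeprank analysis report",
            f"version: {report.provenance.get('version')}",
            f"seed: {report.provenance.get('seed')}",
            f"config hash: {report.provenance.get('config_hash')}",
            f"records: {report.provenance.get('n_records')}",
            "",
            "Full vs control likelihood-ratio tests:",
            report.lrt_table.to_string(index=False),
        ]
        if report.bias_table is not None:
            lines += ["", "Publication-bias tests:", report.bias_table.to_string(index=False)]
        excl = report.provenance.get("exclusions") or []
        lines += ["", f"Exclusions ({len(excl)}):"] + [f"  - {e}" for e in excl]
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
        written.append(p)
    return written
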