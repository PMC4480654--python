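"""End-to-end replay: simulate (or load) a dataset, run every analysis stage.

Stages mirror the analysis battery: pairwise and lineage-specific dN/dS
with their inclusion filters, the neutrality index, exon-edge trimming
with matched randomization at k in {10, 20, 30}, expression covariates,
the splicing index, and the correlation tables.  Every run emits a JSON
manifest recording the seed, thresholds, package version, and a sha256
per output table; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    GeneAlignment,
    SnpRecord,
    TrioAlignment,
    read_expression_matrix,
    read_gene_alignment,
    read_snp_table,
)
from .correlations import (
    compare_dependent_correlations,
    proportion_shift_test,
    spearman,
    partial_spearman,
)
from .lineage import DN_MAX, DS_MAX, DS_MIN, estimate_lineage
from .metrics import covariate_table
from .pairwise import MIN_ALIGNED_BASES, estimate_pairwise
from .polymorphism import neutrality_result
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .splicing import read_est_chains, splicing_index
from .trimming import (
    BOTH_EDGES,
    TrimSpec,
    build_trim_profile,
    randomization_test,
    rho_randomization,
)

log = logging.getLogger("exonedge")

PAIR_INGROUP = (TrioAlignment.INGROUP1, TrioAlignment.INGROUP2)
PAIR_OUTGROUP = (TrioAlignment.INGROUP1, TrioAlignment.OUTGROUP)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and run settings; defaults follow the analysis protocol."""

    out_dir: str = "exonedge_out"
    seed: int = 0
    data_dir: str | None = None       # None -> simulate
    n_genes: int = 200
    min_aligned_bases: int = MIN_ALIGNED_BASES
    ds_min: float = DS_MIN
    ds_max: float = DS_MAX
    dn_max: float = DN_MAX
    trim_ks: tuple[int, ...] = (10, 20, 30)
    trim_mode: str = BOTH_EDGES
    randomizations: int = 1000
    log_base: float = math.e
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Flat key=value TOML; unknown keys rejected, nested sim keys prefixed ``sim_``."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kw = {k[4:]: v for k, v in raw.items() if k.startswith("sim_")}
    pipe_kw = {k: v for k, v in raw.items() if not k.startswith("sim_")}
    if "trim_ks" in pipe_kw:
        pipe_kw["trim_ks"] = tuple(pipe_kw["trim_ks"])
    sim = SimulationConfig(**sim_kw) if sim_kw else SimulationConfig()
    return PipelineConfig(simulation=sim, **pipe_kw)


@dataclass
class DataBundle:
    alignments: list[TrioAlignment]
    snps: list[SnpRecord] | None
    expression: pd.DataFrame | None
    est_chains: dict | None
    truth: pd.DataFrame | None = None


def as_trio(g: GeneAlignment) -> TrioAlignment:
    return TrioAlignment(
        gene_id=g.gene_id,
        reference_species=TrioAlignment.INGROUP1,
        sequences=g.sequences,
        exon_blocks=g.exon_blocks,
        internal_stop=g.internal_stop,
        source_codons=g.source_codons,
    )


def load_data(data_dir: str | Path) -> DataBundle:
    """Read a dataset directory in the dialect ``write_dataset`` emits."""
    d = Path(data_dir)
    exon_map = d / "exon_map.tsv"
    alignments = [
        as_trio(read_gene_alignment(f, exon_map))
        for f in sorted((d / "alignments").glob("*.fasta"))
    ]
    snps = read_snp_table(d / "snps.tsv") if (d / "snps.tsv").exists() else None
    expr = (
        read_expression_matrix(d / "expression.tsv")
        if (d / "expression.tsv").exists()
        else None
    )
    ests = (
        read_est_chains(d / "est_chains.tsv")
        if (d / "est_chains.tsv").exists()
        else None
    )
    truth = (
        pd.read_csv(d / "truth.tsv", sep="\t", comment="#")
        if (d / "truth.tsv").exists()
        else None
    )
    return DataBundle(alignments, snps, expr, ests, truth)


def bundle_from_simulation(cfg: PipelineConfig) -> DataBundle:
    sim_cfg = cfg.simulation
    if sim_cfg.n_genes != cfg.n_genes:
        sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "n_genes": cfg.n_genes})
    ds = simulate_dataset(sim_cfg, cfg.seed)
    return DataBundle(ds.alignments, ds.snps, ds.expression, ds.est_chains)


def pairwise_table(
    alignments: list[TrioAlignment], pair: tuple[str, str], min_aligned: int
) -> pd.DataFrame:
    rows = []
    for g in alignments:
        e = estimate_pairwise(g, pair, min_aligned)
        rows.append(
            {
                "gene_id": e.gene_id, "Sd": e.Sd, "Nd": e.Nd, "S": e.S, "N": e.N,
                "dN": e.dN, "dS": e.dS, "omega": e.omega,
                "n_codons_used": e.n_codons_used, "aligned_bases": e.aligned_bases,
                "valid": e.valid, "reason": e.reason,
            }
        )
    return pd.DataFrame(rows)


def lineage_table(alignments: list[TrioAlignment], cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for g in alignments:
        for br, e in estimate_lineage(
            g, cfg.min_aligned_bases, cfg.ds_min, cfg.ds_max, cfg.dn_max
        ).items():
            rows.append(
                {
                    "gene_id": e.gene_id, "branch": br, "Sd": e.Sd, "Nd": e.Nd,
                    "dN": e.dN, "dS": e.dS, "omega": e.omega,
                    "valid": e.valid, "reason": e.reason,
                }
            )
    return pd.DataFrame(rows)


def neutrality_table(
    alignments: list[TrioAlignment],
    pairwise: pd.DataFrame,
    snps: list[SnpRecord],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    by_gene = {g.gene_id: g for g in alignments}
    rows = []
    for r in pairwise[pairwise["valid"]].itertuples(index=False):
        g = by_gene[r.gene_id]
        est = estimate_pairwise(g, PAIR_INGROUP, cfg.min_aligned_bases)
        ni = neutrality_result(g, est, snps, cfg.log_base)
        rows.append(
            {
                "gene_id": ni.gene_id, "Ds": ni.Ds, "Dn": ni.Dn,
                "Ps": ni.Ps, "Pn": ni.Pn, "NI": ni.NI,
            }
        )
    return pd.DataFrame(rows)


def trim_tables(
    alignments: list[TrioAlignment],
    snps: list[SnpRecord] | None,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene randomization results for each k, plus the proportion-shift table."""
    stats = ("dN", "dS", "omega", "NI") if snps is not None else ("dN", "dS", "omega")
    rows, shift_rows = [], []
    for k in cfg.trim_ks:
        spec = TrimSpec(k=k, mode=cfg.trim_mode, min_post_trim_bases=cfg.min_aligned_bases)
        above_before = above_seq = above_rand = n_elig = 0
        for i, g in enumerate(alignments):
            rng = np.random.default_rng([cfg.seed, 7, k, i])
            res = randomization_test(
                g, spec, stats, cfg.randomizations, rng,
                pair=PAIR_INGROUP, snps=snps, log_base=cfg.log_base,
            )
            if res is None:
                continue
            tp = build_trim_profile(g, spec, PAIR_INGROUP, snps, cfg.log_base)
            untrimmed = tp.statistics(np.arange(tp.n_codons), stats)
            n_elig += 1
            om_seq = res["omega"].observed_sequential
            om_rand = res["omega"].null_values[0]
            if np.isfinite(untrimmed["omega"]) and untrimmed["omega"] > 1:
                above_before += 1
            if np.isfinite(om_seq) and om_seq > 1:
                above_seq += 1
            if np.isfinite(om_rand) and om_rand > 1:
                above_rand += 1
            for stat in stats:
                r = res[stat]
                rows.append(
                    {
                        "gene_id": g.gene_id, "k": k, "statistic": stat,
                        "untrimmed": untrimmed[stat],
                        "observed_sequential": r.observed_sequential,
                        "null_median": float(np.nanmedian(r.null_values)),
                        "q": r.q, "p": r.p, "s": r.s, "unreliable": r.unreliable,
                    }
                )
        shift = proportion_shift_test(above_before, above_seq, n_elig) if n_elig else None
        shift_rows.append(
            {
                "k": k, "n_genes": n_elig,
                "pct_above1_untrimmed": 100 * above_before / n_elig if n_elig else np.nan,
                "pct_above1_sequential": 100 * above_seq / n_elig if n_elig else np.nan,
                "pct_above1_random": 100 * above_rand / n_elig if n_elig else np.nan,
                "chi2": shift.chi2 if shift else np.nan,
                "p": shift.p if shift else np.nan,
                "applicable": bool(shift.applicable) if shift else False,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(shift_rows)


def splice_table(est_chains: dict, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for i, (gid, chains) in enumerate(sorted(est_chains.items())):
        si = splicing_index(chains, rng=np.random.default_rng([cfg.seed, 9, i]))
        rows.append(
            {
                "gene_id": gid, "n_ests": si.n_ests, "index": si.index,
                "excluded": si.excluded,
            }
        )
    return pd.DataFrame(rows)


def _gene_frame(
    pair_in: pd.DataFrame,
    pair_out: pd.DataFrame,
    lineage: pd.DataFrame,
    ni: pd.DataFrame | None,
    covariates: pd.DataFrame,
    splice: pd.DataFrame | None,
) -> pd.DataFrame:
    """Wide per-gene table joining every rate estimate and covariate."""
    def valid_series(df: pd.DataFrame, col: str, name: str) -> pd.Series:
        ok = df[df["valid"]] if "valid" in df else df
        return ok.set_index("gene_id")[col].rename(name)

    parts = [
        valid_series(pair_in, "omega", "omega_pair_ingroup"),
        valid_series(pair_out, "omega", "omega_pair_outgroup"),
        valid_series(
            lineage[lineage["branch"] == TrioAlignment.INGROUP1],
            "omega", "omega_lineage",
        ),
    ]
    if ni is not None and not ni.empty:
        parts.append(ni.set_index("gene_id")["NI"].rename("NI"))
    if splice is not None and not splice.empty:
        ok = splice[~splice["excluded"]]
        parts.append(ok.set_index("gene_id")["index"].rename("splicing_index"))
    wide = pd.concat(parts, axis=1)
    return wide.join(covariates, how="left")


def correlation_tables(gene_frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rate-vs-covariate Spearman matrix, partial matrix, dependent comparison."""
    rate_vars = [
        c for c in ("omega_pair_ingroup", "omega_pair_outgroup", "omega_lineage", "NI")
        if c in gene_frame
    ]
    covars = [
        c for c in ("expression_level", "expression_z", "breadth", "tau", "splicing_index")
        if c in gene_frame
    ]
    t1 = []
    for rv in rate_vars:
        for cv in covars:
            try:
                r = spearman(gene_frame[cv], gene_frame[rv], (cv, rv))
            except ValueError:
                continue
            t1.append({"rate": rv, "covariate": cv, "rho": r.rho, "n": r.n, "p": r.p})
    t2 = []
    for rv in rate_vars:
        for cv in covars:
            if cv == "expression_level":
                continue
            try:
                r = partial_spearman(
                    gene_frame[cv], gene_frame[rv], gene_frame["expression_level"], (cv, rv)
                )
            except ValueError:
                continue
            t2.append({"rate": rv, "covariate": cv, "rho": r.rho, "n": r.n, "p": r.p})
    dep_rows = []
    if {"omega_pair_ingroup", "omega_lineage"} <= set(gene_frame.columns):
        sub = gene_frame[
            ["expression_level", "omega_pair_ingroup", "omega_lineage"]
        ].dropna()
        if len(sub) >= 4:
            ra = spearman(sub["expression_level"], sub["omega_pair_ingroup"]).rho
            rb = spearman(sub["expression_level"], sub["omega_lineage"]).rho
            rab = spearman(sub["omega_pair_ingroup"], sub["omega_lineage"]).rho
            cmp_ = compare_dependent_correlations(ra, rb, rab, len(sub))
            dep_rows.append(
                {
                    "shared": "expression_level",
                    "rho_pairwise": ra, "rho_lineage": rb, "rho_between": rab,
                    "t": cmp_.t_stat, "df": cmp_.df, "p": cmp_.p, "method": cmp_.method,
                }
            )
    return pd.DataFrame(t1), pd.DataFrame(t2), pd.DataFrame(dep_rows)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index, float_format="%.6f")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = load_data(cfg.data_dir) if cfg.data_dir else bundle_from_simulation(cfg)
    filter_counts = [{"stage": "input", "n_in": len(data.alignments), "n_out": len(data.alignments)}]
    hashes: dict[str, str] = {}

    pair_in = pairwise_table(data.alignments, PAIR_INGROUP, cfg.min_aligned_bases)
    pair_out = pairwise_table(data.alignments, PAIR_OUTGROUP, cfg.min_aligned_bases)
    hashes["pairwise_ingroup.tsv"] = _write(pair_in, out / "pairwise_ingroup.tsv")
    hashes["pairwise_outgroup.tsv"] = _write(pair_out, out / "pairwise_outgroup.tsv")
    filter_counts.append(
        {"stage": "pairwise_ingroup_valid", "n_in": len(pair_in), "n_out": int(pair_in["valid"].sum())}
    )

    lin = lineage_table(data.alignments, cfg)
    hashes["lineage.tsv"] = _write(lin, out / "lineage.tsv")
    focal = lin[lin["branch"] == TrioAlignment.INGROUP1]
    filter_counts.append(
        {"stage": "lineage_focal_valid", "n_in": len(focal), "n_out": int(focal["valid"].sum())}
    )

    ni = None
    if data.snps is not None:
        ni = neutrality_table(data.alignments, pair_in, data.snps, cfg)
        hashes["neutrality.tsv"] = _write(ni, out / "neutrality.tsv")
    else:
        log.warning("no SNP table: neutrality-index stage skipped")

    trim, table3 = trim_tables(data.alignments, data.snps, cfg)
    hashes["trim_randomization.tsv"] = _write(trim, out / "trim_randomization.tsv")
    hashes["proportion_shift.tsv"] = _write(table3, out / "proportion_shift.tsv")

    cov = splice = None
    if data.expression is not None:
        cov = covariate_table(data.expression)
        hashes["covariates.tsv"] = _write(cov, out / "covariates.tsv", index=True)
    if data.est_chains:
        splice = splice_table(data.est_chains, cfg)
        hashes["splicing_index.tsv"] = _write(splice, out / "splicing_index.tsv")

    if cov is not None:
        gf = _gene_frame(pair_in, pair_out, lin, ni, cov, splice)
        t1, t2, dep = correlation_tables(gf)
        hashes["correlations.tsv"] = _write(t1, out / "correlations.tsv")
        hashes["partial_correlations.tsv"] = _write(t2, out / "partial_correlations.tsv")
        if not dep.empty:
            hashes["dependent_correlations.tsv"] = _write(dep, out / "dependent_correlations.tsv")

        # correlation-attenuation randomization at the deepest trim
        k = max(cfg.trim_ks)
        spec = TrimSpec(k=k, mode=cfg.trim_mode, min_post_trim_bases=cfg.min_aligned_bases)
        profiles, covariate = [], []
        expr = cov["expression_level"]
        for g in data.alignments:
            profiles.append(build_trim_profile(g, spec, PAIR_INGROUP, data.snps, cfg.log_base))
            covariate.append(expr.get(g.gene_id, np.nan))
        try:
            rr = rho_randomization(
                profiles, np.array(covariate), "omega", cfg.randomizations,
                np.random.default_rng([cfg.seed, 11, k]),
            )
            rho_df = pd.DataFrame(
                [
                    {
                        "k": k, "statistic": "omega", "covariate": "expression_level",
                        "rho_sequential": rr.observed_sequential,
                        "rho_random_median": float(np.nanmedian(rr.null_values)),
                        "q": rr.q, "p": rr.p, "s": rr.s, "unreliable": rr.unreliable,
                    }
                ]
            )
            hashes["rho_randomization.tsv"] = _write(rho_df, out / "rho_randomization.tsv")
        except ValueError as exc:
            log.warning("rho randomization skipped: %s", exc)

    hashes["filter_counts.tsv"] = _write(pd.DataFrame(filter_counts), out / "filter_counts.tsv")
    manifest = {
        "package": "exonedge",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_aligned_bases": cfg.min_aligned_bases,
            "ds_min": cfg.ds_min, "ds_max": cfg.ds_max, "dn_max": cfg.dn_max,
        },
        "trim_ks": list(cfg.trim_ks),
        "trim_mode": cfg.trim_mode,
        "randomizations": cfg.randomizations,
        "tables": hashes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
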