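"""Joins methylation, accessibility and expression variability into the
two-state gene model and emits the pipeline's summary tables.

The two states operationalize the study's integrative picture:
methylated/stable genes (high gene-body methylation, low expression
variability, typically limited accessibility) versus low-methylated /
variable genes (open chromatin, variable expression).  The state rules
are an explicit operationalization, labelled as such in output headers;
they are not a claim about mechanism.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STATE_METH_STABLE = "methylated_stable"
STATE_LOW_VARIABLE = "low_meth_variable"
STATE_UNASSIGNED = "unassigned"


class ReportError(RuntimeError):
    """A required pipeline stage output is missing."""


def assign_states(
    summaries: pd.DataFrame,
    variability: pd.DataFrame,
    accessibility: pd.DataFrame | None = None,
    stable_quintiles: Sequence[int] = (1, 2),
    variable_quintiles: Sequence[int] = (4, 5),
    figure_faithful: bool = False,
) -> pd.DataFrame:
    """Assign each gene to one of the two integrative states.

    methylated_stable: methylation class 'high' and CV quintile in
    ``stable_quintiles``; low_meth_variable: class 'low' or 'unmethylated'
    and CV quintile in ``variable_quintiles``; anything else (including
    genes missing any input) is unassigned with a reason.
    ``figure_faithful`` restricts the quintile sets to {1} and {5}.
    """
    if figure_faithful:
        stable_quintiles, variable_quintiles = (1,), (5,)
    df = summaries[["gene_id", "mean_ratio", "meth_class"]].merge(
        variability[["gene_id", "cv", "cv_quintile"]], on="gene_id", how="outer"
    )
    if accessibility is not None:
        df = df.merge(accessibility[["gene_id", "tss_signal"]], on="gene_id", how="left")
    else:
        df["tss_signal"] = np.nan
    states, reasons = [], []
    for row in df.itertuples():
        if not isinstance(row.meth_class, str) or row.meth_class == "insufficient":
            states.append(STATE_UNASSIGNED)
            reasons.append("no_methylation_summary")
        elif pd.isna(row.cv_quintile):
            states.append(STATE_UNASSIGNED)
            reasons.append("no_variability")
        elif row.meth_class == "high" and int(row.cv_quintile) in stable_quintiles:
            states.append(STATE_METH_STABLE)
            reasons.append("")
        elif row.meth_class in ("low", "unmethylated") and int(row.cv_quintile) in variable_quintiles:
            states.append(STATE_LOW_VARIABLE)
            reasons.append("")
        else:
            states.append(STATE_UNASSIGNED)
            reasons.append("intermediate")
    df["state"] = states
    df["reason"] = reasons
    return df


def housekeeping_contrast(
    summaries: pd.DataFrame,
    hk_flags: Mapping[str, bool] | pd.Series,
) -> dict:
    """Compare gene-body methylation between housekeeping and other genes.

    Returns per-group medians and a two-sided Mann-Whitney rank-sum test;
    with a single flagged gene the distributions are still reported but the
    test is skipped with a warning note.  Raises with no flagged genes.
    """
    flags = pd.Series(hk_flags)
    df = summaries[summaries["meth_class"] != "insufficient"].copy()
    df["housekeeping"] = df["gene_id"].isin({g for g, f in flags.items() if f})
    hk = df.loc[df["housekeeping"], "mean_ratio"].dropna()
    other = df.loc[~df["housekeeping"], "mean_ratio"].dropna()
    if len(hk) == 0:
        raise ValueError("no housekeeping-flagged genes in the annotation")
    out = {
        "n_hk": int(len(hk)),
        "n_other": int(len(other)),
        "median_hk": float(hk.median()),
        "median_other": float(other.median()),
    }
    if len(hk) < 2 or len(other) < 2:
        out.update({"statistic": np.nan, "p_value": np.nan,
                    "note": "test skipped: too few genes in a group"})
    else:
        res = stats.mannwhitneyu(hk, other, alternative="two-sided")
        out.update({"statistic": float(res.statistic), "p_value": float(res.pvalue),
                    "note": ""})
    return out


REQUIRED_STAGES = (
    "gene_methylation",
    "variability",
    "metagene",
    "states",
)


def build_report(
    outputs: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    config_json: Optional[str] = None,
    seed: Optional[int] = None,
    extra_tables: Mapping[str, pd.DataFrame] | None = None,
) -> Path:
    """Write all stage tables plus a run manifest to ``outdir``.

    ``outputs`` must contain every stage in :data:`REQUIRED_STAGES`;
    a missing stage raises :class:`ReportError` naming it.  Tables are
    written deterministically (sorted columns preserved, fixed float
    format) so a rerun with the same seed and config is byte-identical.
    The manifest records package versions, the seed, a config hash and the
    sha256 of every emitted table.
    """
    missing = [s for s in REQUIRED_STAGES if s not in outputs]
    if missing:
        raise ReportError(f"missing stage output(s): {', '.join(missing)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_tables = dict(outputs)
    if extra_tables:
        all_tables.update(extra_tables)
    hashes = {}
    for name, table in sorted(all_tables.items()):
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# gbmethyl report table: {name}"
                     " (state rules are an operationalization of the"
                     " two-state gene model)\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.8g")
        hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    from . import __version__

    manifest = {
        "package": "gbmethyl",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(config_json.encode()).hexdigest() if config_json else None
        ),
        "tables": hashes,
        "stages": sorted(all_tables),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def run_end_to_end(config, outdir: str | Path) -> Path:
    """Run the whole pipeline on one synthetic study and emit the report.

    Generates the study from ``config`` (fully seeded), calls methylation,
    summarizes the methylome, computes expression variability, extracts
    TSS accessibility, tests species differential methylation, assigns the
    two-state model and writes every table plus the manifest to ``outdir``.
    """
    from . import accessibility as acc
    from . import diff_methylation as dm
    from . import expression_variability as ev
    from . import methylome_features as mf
    from . import synthetic_data as sd

    rng = np.random.default_rng(config.seed)
    genome, annotation, truth = sd.generate_genome(config, rng)

    counts_a = sd.generate_site_counts(truth.cpg_sites, config, rng)
    sites_a = sd.retained_sites(counts_a)
    counts_b = sd.generate_site_counts(sd.species_b_truth(truth), config, rng)
    sites_b = sd.retained_sites(counts_b)

    summaries = mf.gene_methylation_table(sites_a, annotation)
    summaries_b = mf.gene_methylation_table(sites_b, annotation)
    features = mf.feature_methylation(sites_a, annotation)
    repeats = mf.repeat_methylation(sites_a, annotation)
    windows = mf.window_methylation(sites_a, genome)
    hist = mf.methylation_histogram(summaries)

    tpm = sd.generate_expression(truth, rng)
    variability = ev.variability_table(tpm, summaries)
    per_rank_cv, cv_trend = ev.cv_by_methylation(variability)

    fragments, peaks = sd.generate_atac(genome, truth, rng)
    genes_tab, cov, valid = acc.tss_coverage(fragments, annotation, genome)
    strata = acc.methylation_strata(summaries)
    profile = acc.metagene(genes_tab, cov, valid, strata)
    flank = cov.shape[1] // 2
    central = np.nanmean(
        np.where(valid, cov, np.nan)[:, flank - 200 : flank + 200], axis=1
    )
    access = pd.DataFrame({"gene_id": genes_tab["gene_id"], "tss_signal": central})
    n_prom, peak_table = acc.peak_promoter_overlap(peaks, annotation)

    dmg = dm.species_dmg(summaries, summaries_b)
    states = assign_states(summaries, variability, access)
    hk = housekeeping_contrast(
        summaries, {g.gene_id: g.housekeeping for g in annotation.genes}
    )

    scalars = pd.DataFrame(
        {
            "quantity": [
                "n_peaks", "n_promoter_peaks", "n_species_dmg",
                "cv_meth_spearman_rho", "hk_median", "non_hk_median",
            ],
            "value": [
                float(len(peaks)), float(n_prom), float(dmg["dmg"].sum()),
                cv_trend["rho"], hk["median_hk"], hk["median_other"],
            ],
        }
    )
    outputs = {
        "gene_methylation": summaries,
        "gene_methylation_species_b": summaries_b,
        "feature_methylation": features,
        "repeat_methylation": repeats,
        "window_methylation": windows,
        "gene_histogram": hist,
        "variability": variability,
        "cv_by_rank": per_rank_cv,
        "metagene": profile,
        "peak_overlap": peak_table,
        "species_dmg": dmg,
        "states": states,
        "summary_scalars": scalars,
    }
    return build_report(outputs, outdir, config_json=config.to_json(), seed=config.seed)
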