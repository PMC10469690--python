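"""Orchestration: per-dataset conservation and community summaries.

``run_conservation`` applies the three per-class statistics (Fritz-Purvis
D, Pagel's lambda on raw counts, consenTRAIT tau_D) across a tree/table
pair and assembles a per-class summary table with a final unweighted
"Average" row — the per-dataset layout used when comparing conservation
of BGC classes between genome collections.  ``run_community`` bundles the
distance-matrix analyses (Mantel, PCoA, PERMANOVA), and
``run_enrichment`` the genus-level negative-binomial contrasts.

Each run carries a manifest with every derived seed and statistical
convention, so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import community as comm
from . import enrichment as enr
from .core import Phylogeny, TraitTable, align_tree_table
from .depth import consentrait
from .signal import d_test, pagel_lambda

logger = logging.getLogger("bgconserve")

_NUMERIC_COLS = [
    "d_obs",
    "D",
    "p_random",
    "p_brownian",
    "lambda_hat",
    "LR",
    "p_lambda",
    "tau_mean",
    "tau_min",
    "tau_max",
    "p_tau",
]


def summarize_average(values) -> float:
    """Unweighted arithmetic mean of the finite entries (the Average row)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to average")
    return float(vals.mean())


def _derived_seed(seed: int, stage: int, index: int) -> int:
    """Per-class, per-stage substream seed (recorded in the manifest)."""
    ss = np.random.SeedSequence([int(seed), int(stage), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ConservationTable:
    """Per-class conservation summary with an Average row.

    ``df`` rows are BGC classes plus a final ``Average`` row; ``results``
    maps class -> the full per-statistic result objects; ``manifest``
    records seeds and conventions.
    """

    df: pd.DataFrame
    results: dict
    manifest: dict

    def rounded(self, decimals: int = 4) -> pd.DataFrame:
        return self.df.round(decimals)


def run_conservation(
    tree: Phylogeny,
    table: TraitTable,
    n_perm: int = 1000,
    seed: int = 42,
    min_fraction: float = 0.9,
    classes: list[str] | None = None,
    align_policy: str = "intersect",
    log1p_lambda: bool = False,
) -> ConservationTable:
    """D, lambda and tau_D for every BGC class of one dataset.

    Classes without presence/absence variation are reported as NA with a
    reason; the Average row is the unweighted mean over non-NA classes.
    Raw counts feed Pagel's lambda (``log1p_lambda`` applies log(1+x)
    first); the binarised table feeds D and tau_D.
    """
    tree, table = align_tree_table(tree, table, policy=align_policy)
    tree = tree.resolve_polytomies(seed=_derived_seed(seed, 0, 0))
    binary = table.binarize()
    names = classes if classes is not None else table.class_names
    rows, results, reasons = [], {}, {}
    for i, name in enumerate(names):
        b = binary.counts[name].to_numpy()
        x = table.counts[name].to_numpy(dtype=float)
        if log1p_lambda:
            x = np.log1p(x)
        row = {c: np.nan for c in _NUMERIC_COLS}
        if b.sum() == 0 or b.sum() == len(b):
            reasons[name] = "no presence/absence variation"
            rows.append(row)
            continue
        dres = d_test(
            tree, b, n_perm=n_perm, seed=_derived_seed(seed, 1, i), trait_name=name
        )
        tres = consentrait(
            tree,
            b,
            min_fraction=min_fraction,
            n_perm=n_perm,
            seed=_derived_seed(seed, 2, i),
            trait_name=name,
        )
        lres = pagel_lambda(tree, x, trait_name=name)
        row.update(
            d_obs=dres.d_obs,
            D=dres.D,
            p_random=dres.p_random,
            p_brownian=dres.p_brownian,
            lambda_hat=lres.lambda_hat,
            LR=lres.LR,
            p_lambda=lres.p_value,
            tau_mean=tres.tau_mean,
            tau_min=tres.tau_min,
            tau_max=tres.tau_max,
            p_tau=tres.p_value,
        )
        results[name] = {"d": dres, "tau": tres, "lambda": lres}
        rows.append(row)
    df = pd.DataFrame(rows, index=names)
    df["sig_D"] = (df["p_random"] < 0.05) & (df["p_brownian"] < 0.05)
    df["sig_tau"] = df["p_tau"] < 0.05
    avg = {c: summarize_average(df[c]) if df[c].notna().any() else np.nan for c in _NUMERIC_COLS}
    df.loc["Average"] = pd.Series(avg)
    manifest = {
        "n_perm": n_perm,
        "seed": seed,
        "min_fraction": min_fraction,
        "derived_seeds": {
            name: {
                "resolve": _derived_seed(seed, 0, 0),
                "d_test": _derived_seed(seed, 1, i),
                "consentrait": _derived_seed(seed, 2, i),
            }
            for i, name in enumerate(names)
        },
        "skipped": reasons,
        "conventions": {
            "p_random/p_brownian": "lower tail (clumping at least as strong), +1 corrected",
            "p_tau": "upper tail (depth at least as large), +1 corrected",
            "lambda_trait": "log1p(counts)" if log1p_lambda else "raw counts",
            "average_row": "unweighted mean over non-NA classes",
        },
    }
    return ConservationTable(df=df, results=results, manifest=manifest)


def run_community(
    tree: Phylogeny,
    table: TraitTable,
    n_perm: int = 1000,
    seed: int = 42,
    group_rank: str = "genus",
    top_k: int | None = None,
    align_policy: str = "intersect",
) -> dict:
    """Mantel (phylogeny vs BGC profile), PCoA and PERMANOVA for a dataset.

    PERMANOVA (and the ordination ellipses) can be restricted to the
    ``top_k`` most genome-rich groups; Mantel and PCoA always use all
    genomes.
    """
    tree, table = align_tree_table(tree, table, policy=align_policy)
    phylo_dm = tree.cophenetic()
    bc_dm = comm.bray_curtis(table)
    mres = comm.mantel(
        phylo_dm, bc_dm, n_perm=n_perm, seed=_derived_seed(seed, 3, 0)
    )
    ores = comm.pcoa(bc_dm)
    out = {"mantel": mres, "pcoa": ores, "permanova": None, "ellipses": None}
    if table.metadata is not None and group_rank in table.metadata.columns:
        groups = table.metadata[group_rank].astype(str)
        ids = list(table.genome_ids)
        if top_k is not None:
            sizes = groups.value_counts()
            keep_groups = set(
                sorted(sizes.index, key=lambda g: (-sizes[g], g))[:top_k]
            )
            ids = [g for g in ids if groups.loc[g] in keep_groups]
        sub_groups = groups.loc[ids].to_numpy()
        out["permanova"] = comm.permanova(
            bc_dm.filter(ids),
            sub_groups,
            n_perm=n_perm,
            seed=_derived_seed(seed, 4, 0),
        )
        if ores.coordinates.shape[1] >= 2:
            out["ellipses"] = comm.group_ellipses(
                ores.coordinates.loc[ids], sub_groups
            )
    out["manifest"] = {
        "n_perm": n_perm,
        "seed": seed,
        "group_rank": group_rank,
        "top_k": top_k,
        "mantel_seed": _derived_seed(seed, 3, 0),
        "permanova_seed": _derived_seed(seed, 4, 0),
    }
    return out


def run_enrichment(
    table: TraitTable,
    reference_genus: str | None = None,
    top_k: int = 7,
    min_group_size: int = 5,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class genus enrichment table (long format, with BH column).

    The reference genus defaults to the most genome-rich genus.  The
    Benjamini-Hochberg column is informational only; significance calls
    use the raw Wald p.
    """
    top = enr.select_top_genera(table, k=top_k)
    if reference_genus is None:
        reference_genus = top[0]
    names = classes if classes is not None else table.class_names
    frames = []
    for name in names:
        try:
            res = enr.nb_enrichment(
                table, name, reference_genus, min_group_size=min_group_size
            )
        except ValueError as exc:
            logger.warning("enrichment skipped for %s: %s", name, exc)
            continue
        sub = res.per_genus.copy()
        sub.insert(0, "class", name)
        sub["dispersion"] = res.dispersion
        sub["converged"] = res.converged
        sub["model"] = res.model
        frames.append(sub)
    if not frames:
        raise ValueError("no class could be fitted")
    df = pd.concat(frames, ignore_index=True)
    from statsmodels.stats.multitest import multipletests

    mask = df["p_value"].notna() & (df["p_value"] < 1.0)
    df["p_bh"] = np.nan
    if mask.any():
        df.loc[mask, "p_bh"] = multipletests(df.loc[mask, "p_value"], method="fdr_bh")[1]
    df.attrs["reference_genus"] = reference_genus
    df.attrs["top_genera"] = top
    return df


def presence_rings(table: TraitTable) -> pd.DataFrame:
    """Long tip/class/presence table (ring-annotation export for tree viewers)."""
    binary = table.binarize().counts
    long = binary.reset_index().melt(
        id_vars=binary.index.name or "index", var_name="class", value_name="present"
    )
    long.columns = ["tip", "class", "present"]
    return long


def write_outputs(
    outdir: str,
    conservation: ConservationTable | None = None,
    community_results: dict | None = None,
    enrichment_df: pd.DataFrame | None = None,
    table: TraitTable | None = None,
) -> None:
    """Write the standard TSV outputs plus a JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {}
    if conservation is not None:
        conservation.df.to_csv(os.path.join(outdir, "conservation_table.tsv"), sep="\t")
        manifest["conservation"] = conservation.manifest
    if community_results is not None:
        m = community_results["mantel"]
        p = community_results["permanova"]
        rows = [
            {"statistic": "mantel_r", "value": m.r_obs, "p_value": m.p_value, "n_perm": m.n_perm}
        ]
        if p is not None:
            rows.append(
                {
                    "statistic": "permanova_pseudo_F",
                    "value": p.pseudo_F,
                    "p_value": p.p_value,
                    "n_perm": p.n_perm,
                }
            )
            rows.append(
                {"statistic": "permanova_R2", "value": p.R2, "p_value": np.nan, "n_perm": p.n_perm}
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "community_stats.tsv"), sep="\t", index=False
        )
        o = community_results["pcoa"]
        coords = o.coordinates.copy()
        coords.to_csv(os.path.join(outdir, "ordination.tsv"), sep="\t")
        pd.DataFrame(
            {"eigenvalue": o.eigenvalues}
        ).to_csv(os.path.join(outdir, "eigenvalues.tsv"), sep="\t", index=False)
        if community_results.get("ellipses") is not None:
            community_results["ellipses"].to_csv(
                os.path.join(outdir, "ellipses.tsv"), sep="\t", index=False
            )
        manifest["community"] = community_results["manifest"]
    if enrichment_df is not None:
        enrichment_df.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        manifest["enrichment"] = {
            "reference_genus": enrichment_df.attrs.get("reference_genus"),
            "top_genera": enrichment_df.attrs.get("top_genera"),
        }
    if table is not None:
        presence_rings(table).to_csv(
            os.path.join(outdir, "presence_rings.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
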