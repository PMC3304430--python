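"""Cytokine quantitation, protein/RNA fold changes and concordance classes.

A species-resolved multiplex panel measures each analyte in pg per ml of
tumour-extract supernatant; dividing out the extract volume and tumour mass
gives pg per g of tumour.  Per analyte the treated/untreated protein fold
change is tested with an unpaired Student's t on log10 concentrations
(immunoassay error is multiplicative), then joined against the matching
species' RNA fold change and classified:

* ``concordant_induced``            -- protein induced (fold >= protein_thresh
                                       and significant) and RNA fold >= fc_thresh;
* ``post_transcriptional_candidate``-- protein induced but RNA essentially
                                       unchanged (the classic G-CSF pattern);
* ``rna_only``                      -- RNA up without a significant protein rise;
* ``unchanged``                     -- everything else.

Also here: species-specific qPCR relative expression, with each target Ct
normalised against the average of the YWHAZ and PPIA housekeeping signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONCORDANCE_CLASSES = (
    "concordant_induced",
    "post_transcriptional_candidate",
    "rna_only",
    "unchanged",
)

HOUSEKEEPING = ("YWHAZ", "PPIA")

PANEL_COLUMNS = (
    "analyte", "species", "gene_symbol", "sample_id", "group",
    "concentration_pg_per_ml", "extract_volume_ml", "tumour_mass_g",
    "lod_pg_per_ml",
)

DEFAULT_EXTRACT_VOLUME_ML = 0.2  # standard homogenisation volume (200 ul)


def read_cytokine_panel(path) -> pd.DataFrame:
    """Read a cytokine panel CSV; a missing extract volume column gets the
    0.2 ml default."""
    df = pd.read_csv(path)
    if "extract_volume_ml" not in df.columns:
        df["extract_volume_ml"] = DEFAULT_EXTRACT_VOLUME_ML
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cytokine panel missing columns {missing}")
    return df


def per_gram_concentration(panel: pd.DataFrame, lod_policy: str = "half") -> pd.DataFrame:
    """Convert measured pg/ml to pg per g of tumour.

    pg_per_g = pg_per_ml * extract_volume_ml / tumour_mass_g.  Measurements
    below the limit of detection (flagged or zero) are imputed first:
    ``half`` -> LOD/2 (default convention), ``zero`` -> 0, ``lod`` -> LOD.
    """
    if lod_policy not in ("half", "zero", "lod"):
        raise ValueError("lod_policy must be half, zero or lod")
    out = panel.copy()
    if out["tumour_mass_g"].isna().any() or (out["tumour_mass_g"] <= 0).any():
        bad = out.loc[out["tumour_mass_g"].isna() | (out["tumour_mass_g"] <= 0)]
        raise ValueError(f"missing or non-positive tumour mass for sample "
                         f"{bad['sample_id'].iloc[0]!r}")
    if (out["extract_volume_ml"] <= 0).any():
        raise ValueError("extract volumes must be positive")
    conc = out["concentration_pg_per_ml"].astype(float).copy()
    below = conc < out["lod_pg_per_ml"]
    if "below_lod" in out.columns:
        below |= out["below_lod"].astype(bool)
    factor = {"half": 0.5, "zero": 0.0, "lod": 1.0}[lod_policy]
    conc[below] = out.loc[below, "lod_pg_per_ml"] * factor
    out["pg_per_g"] = conc * out["extract_volume_ml"] / out["tumour_mass_g"]
    return out


def fold_and_test(panel_pg_per_g: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-analyte protein fold change (treated / untreated group means of
    pg/g) with a two-sided unpaired Student's t on log10 concentrations.

    Zero values (possible under the ``zero`` LOD policy) are floored at a
    tenth of the smallest positive value before taking logs.
    """
    rows = []
    for (analyte, species), sub in panel_pg_per_g.groupby(["analyte", "species"], sort=False):
        untreated = sub.loc[sub["group"] == "untreated", "pg_per_g"].to_numpy(float)
        treated = sub.loc[sub["group"] == "treated", "pg_per_g"].to_numpy(float)
        if len(untreated) < 2 or len(treated) < 2:
            raise ValueError(f"analyte {analyte!r}: need >= 2 samples per group")
        mean_u, mean_t = float(np.mean(untreated)), float(np.mean(treated))
        if mean_u <= 0:
            fold = np.nan
            p = np.nan
            flagged = True
        else:
            fold = mean_t / mean_u
            pos = np.concatenate([untreated, treated])
            floor = pos[pos > 0].min() * 0.1 if (pos > 0).any() else 1e-12
            lu = np.log10(np.maximum(untreated, floor))
            lt = np.log10(np.maximum(treated, floor))
            if np.ptp(lu) == 0 and np.ptp(lt) == 0 and np.mean(lu) == np.mean(lt):
                p = 1.0
            else:
                p = float(stats.ttest_ind(lt, lu, equal_var=True).pvalue)
            flagged = False
        rows.append({
            "analyte": analyte,
            "species": species,
            "gene_symbol": sub["gene_symbol"].iloc[0],
            "mean_untreated_pg_per_g": mean_u,
            "mean_treated_pg_per_g": mean_t,
            "protein_fold": fold,
            "protein_p": p,
            "protein_significant": bool(np.isfinite(p) and p <= alpha),
            "flagged": flagged,
        })
    return pd.DataFrame(rows)


def classify_concordance(
    protein_fold: float,
    protein_significant: bool,
    rna_fold: float,
    fc_thresh: float = 1.5,
    protein_thresh: float = 2.0,
) -> str:
    """Protein-RNA concordance class for one analyte; see module docstring.

    ``rna_fold`` may be NaN (analyte not measurable on the chip), in which
    case the class is computed from the protein evidence alone.
    """
    protein_up = (
        np.isfinite(protein_fold)
        and protein_fold >= protein_thresh
        and protein_significant
    )
    rna_up = np.isfinite(rna_fold) and rna_fold >= fc_thresh
    if protein_up and rna_up:
        return "concordant_induced"
    if protein_up:
        return "post_transcriptional_candidate"
    if rna_up:
        return "rna_only"
    return "unchanged"


def build_concordance_table(
    panel_pg_per_g: pd.DataFrame,
    de_results: dict[str, pd.DataFrame],
    probeset_symbols: dict[str, dict[str, str | None]],
    fc_thresh: float = 1.5,
    protein_thresh: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join protein folds with species-matched RNA folds and classify.

    ``de_results`` maps species to a moderated-t result table;
    ``probeset_symbols`` maps species -> probeset_id -> gene symbol.  The RNA
    fold of an analyte is the signed fold change of the probe set annotated
    with its gene symbol (NaN if none matches).  Rows come back in the
    classic table order: RNA fold descending.
    """
    protein = fold_and_test(panel_pg_per_g, alpha=alpha)
    if protein["analyte"].duplicated().any():
        dup = protein.loc[protein["analyte"].duplicated(), "analyte"].iloc[0]
        raise ValueError(f"duplicate analyte name {dup!r}")
    rna_lookup: dict[tuple[str, str], float] = {}
    for species, de in de_results.items():
        symbols = probeset_symbols.get(species, {})
        for _, row in de.iterrows():
            sym = symbols.get(row["probeset_id"])
            if not sym:
                continue
            signed = 2.0 ** row["log2fc"]
            key = (species, sym)
            # keep the most significant probe set per symbol
            if key not in rna_lookup or row["p"] < rna_lookup[key][1]:
                rna_lookup[key] = (signed, row["p"])
    rows = []
    for _, r in protein.iterrows():
        key = (r["species"], r["gene_symbol"])
        rna_fold = rna_lookup.get(key, (np.nan, np.nan))[0]
        cls = classify_concordance(
            r["protein_fold"], r["protein_significant"], rna_fold,
            fc_thresh=fc_thresh, protein_thresh=protein_thresh,
        )
        rows.append({
            "analyte": r["analyte"],
            "species": r["species"],
            "gene_symbol": r["gene_symbol"],
            "protein_fold": r["protein_fold"],
            "protein_p": r["protein_p"],
            "rna_fold": rna_fold,
            "class_": cls,
        })
    out = pd.DataFrame(rows)
    return out.sort_values("rna_fold", ascending=False, na_position="last",
                           kind="mergesort").reset_index(drop=True)


def write_concordance_table(table: pd.DataFrame, path) -> None:
    cols = ["analyte", "gene_symbol", "protein_fold", "rna_fold", "class_",
            "protein_p", "species"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.4g")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_relative_expression(qpcr: pd.DataFrame, target: str) -> dict[str, float]:
    """Relative expression of one qPCR target, treated vs untreated.

    Expects columns sample_id, group, species, and one Ct column per gene
    including both housekeeping genes.  Per sample,
    dCt = Ct_target - mean(Ct_YWHAZ, Ct_PPIA); the relative quantity is
    2^-(mean dCt_treated - mean dCt_untreated).  Samples missing a
    housekeeping Ct are dropped with a warning.
    Returns {'dct_untreated', 'dct_treated', 'relative_quantity'}.
    """
    for col in (target, *HOUSEKEEPING):
        if col not in qpcr.columns:
            raise ValueError(f"qPCR table missing Ct column {col!r}")
    df = qpcr.copy()
    bad = df[list(HOUSEKEEPING)].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} sample(s) with missing housekeeping Ct"
        )
        df = df[~bad]
    hk = df[list(HOUSEKEEPING)].mean(axis=1)
    dct = df[target] - hk
    out = {}
    for group in ("untreated", "treated"):
        vals = dct[df["group"] == group]
        if vals.empty:
            raise ValueError(f"no usable samples in group {group!r}")
        out[f"dct_{group}"] = float(vals.mean())
    out["relative_quantity"] = float(
        2.0 ** (-(out["dct_treated"] - out["dct_untreated"]))
    )
    return out


__all__ = [
    "CONCORDANCE_CLASSES",
    "DEFAULT_EXTRACT_VOLUME_ML",
    "HOUSEKEEPING",
    "build_concordance_table",
    "classify_concordance",
    "fold_and_test",
    "per_gram_concentration",
    "qpcr_relative_expression",
    "read_cytokine_panel",
    "write_concordance_table",
]
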