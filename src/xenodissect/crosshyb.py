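"""Cross-species hybridisation classification from the four control arrays.

Hybridising each species' control RNA to each chip gives, per chip, an
own-species array (everything should light up) and an other-species array
(only probe sets able to capture foreign RNA should light up).  Each probe
set is classified as:

* ``cross_hyb``      -- its other-species-RNA signal exceeds tau_x;
* ``safe``           -- not cross_hyb AND it has an ortholog whose own-species
                        control signal on the other chip exceeds tau_p (the
                        foreign transcript was present and therefore capable
                        of producing a cross-hybridising signal);
* ``indeterminate``  -- everything else, including probe sets with no ortholog
                        mapping, for which presence of the foreign transcript
                        cannot be verified (a deliberately conservative rule).

Thresholds are robust array-relative statistics -- centre (median) plus k
times the normal-consistent MAD of the summarised array -- rather than
absolute intensities; both k factors are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .iotables import HUMAN, MOUSE, OrthologMap, ProbesetMap
from .preprocess import ExpressionMatrix

CLASSES = ("cross_hyb", "safe", "indeterminate")


@dataclass(frozen=True)
class DetectionThresholds:
    """k-factors for the two robust detection thresholds.

    tau_x (cross-hybridisation call, on the other-species-RNA array) and
    tau_p (ortholog presence, on the other chip's own-species array) are each
    computed as median + k * MAD_sigma of that array's summarised values,
    where MAD_sigma is the median absolute deviation scaled to be consistent
    for a normal sigma.  Explicit absolute thresholds override the k-rule.
    """

    k_x: float = 2.0
    k_p: float = 2.0
    tau_x: float | None = None  # absolute log2 threshold, overrides k_x
    tau_p: float | None = None

    def threshold(self, values: np.ndarray, which: str) -> float:
        fixed = self.tau_x if which == "x" else self.tau_p
        if fixed is not None:
            return float(fixed)
        k = self.k_x if which == "x" else self.k_p
        centre = float(np.median(values))
        mad = float(stats.median_abs_deviation(values, scale="normal"))
        return centre + k * mad


@dataclass
class CrossHybTable:
    """Per-probe-set species-specificity classes with the evidence used."""

    table: pd.DataFrame  # probeset_id, chip_species, class_, signals, thresholds

    def __post_init__(self) -> None:
        bad = set(self.table["class_"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown classes {bad}")

    def classes(self, chip_species: str) -> pd.Series:
        t = self.table
        sub = t[t["chip_species"] == chip_species]
        return sub.set_index("probeset_id")["class_"]

    def ids_of(self, chip_species: str, class_: str) -> list[str]:
        t = self.table
        m = (t["chip_species"] == chip_species) & (t["class_"] == class_)
        return list(t.loc[m, "probeset_id"])


def _mean_expression(em: ExpressionMatrix) -> pd.Series:
    """Mean summarised log2 expression across an array's replicates."""
    return em.values.mean(axis=1)


def call_crosshyb(
    control_expr: dict[tuple[str, str], ExpressionMatrix],
    probeset_maps: dict[str, ProbesetMap],
    om: OrthologMap,
    thresholds: DetectionThresholds | None = None,
) -> CrossHybTable:
    """Classify every probe set on both chips from the four control arrays.

    ``control_expr`` is keyed by (chip_species, rna_source), with rna_source
    in {human_only, mouse_only}; all four configurations must be present.
    """
    thresholds = thresholds or DetectionThresholds()
    required = {
        (HUMAN, "human_only"), (HUMAN, "mouse_only"),
        (MOUSE, "mouse_only"), (MOUSE, "human_only"),
    }
    missing = required - set(control_expr)
    if missing:
        raise ValueError(f"missing control configurations: {sorted(missing)}")

    rows = []
    for chip, other in ((HUMAN, MOUSE), (MOUSE, HUMAN)):
        other_rna = _mean_expression(control_expr[(chip, f"{other}_only")])
        own_on_other_chip = _mean_expression(control_expr[(other, f"{other}_only")])
        tau_x = thresholds.threshold(other_rna.to_numpy(), "x")
        tau_p = thresholds.threshold(own_on_other_chip.to_numpy(), "p")
        pm = probeset_maps[chip]
        sym_to_ps_other = {}
        pm_other = probeset_maps[other]
        for ps in pm_other.probeset_ids:
            sym = pm_other.symbol_of(ps)
            if sym:
                sym_to_ps_other.setdefault(sym, ps)
        for ps in other_rna.index:
            signal = float(other_rna[ps])
            sym = pm.symbol_of(ps)
            orth = om.ortholog(sym, chip) if sym else None
            ps_orth = sym_to_ps_other.get(orth) if orth else None
            orth_signal = (
                float(own_on_other_chip[ps_orth])
                if ps_orth is not None and ps_orth in own_on_other_chip.index
                else np.nan
            )
            if signal > tau_x:
                cls = "cross_hyb"
            elif np.isfinite(orth_signal) and orth_signal > tau_p:
                cls = "safe"
            else:
                cls = "indeterminate"
            rows.append({
                "probeset_id": ps,
                "chip_species": chip,
                "class_": cls,
                "other_species_signal": signal,
                "ortholog_same_species_signal": orth_signal,
                "tau_x": tau_x,
                "tau_p": tau_p,
            })
    return CrossHybTable(pd.DataFrame(rows))


def summarize_crosshyb(t: CrossHybTable) -> pd.DataFrame:
    """Counts and chip fractions per class and species; empty classes report 0."""
    rows = []
    for chip in (HUMAN, MOUSE):
        sub = t.table[t.table["chip_species"] == chip]
        total = len(sub)
        if total == 0:
            continue
        for cls in CLASSES:
            n = int((sub["class_"] == cls).sum())
            rows.append({
                "chip_species": chip,
                "class_": cls,
                "count": n,
                "fraction": n / total,
                "chip_total": total,
            })
    return pd.DataFrame(rows)


def write_crosshyb_table(t: CrossHybTable, path: str | Path) -> None:
    t.table.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_crosshyb_table(path: str | Path) -> CrossHybTable:
    return CrossHybTable(pd.read_csv(Path(path), sep="\t"))


def write_class_lists(t: CrossHybTable, directory: str | Path) -> list[Path]:
    """Emit the two classic plain-text probe-set lists per chip: probe sets
    with cross-hybridisation potential, and probe sets unlikely to
    cross-hybridise."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for chip in (HUMAN, MOUSE):
        for cls, label in (("cross_hyb", "crosshyb_potential"), ("safe", "unlikely_crosshyb")):
            path = directory / f"{chip}_{label}.txt"
            path.write_text("\n".join(t.ids_of(chip, cls)) + "\n", encoding="utf-8")
            written.append(path)
    return written


__all__ = [
    "CLASSES",
    "CrossHybTable",
    "DetectionThresholds",
    "call_crosshyb",
    "read_crosshyb_table",
    "summarize_crosshyb",
    "write_class_lists",
    "write_crosshyb_table",
]
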