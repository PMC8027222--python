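"""Cross-dataset integration: classify genes as pheromone-responsive in both
mating types (SRB), only in MT+ (SRP), only in MT- (SRM), non-responsive, or
unclassified.

The integration couples confirmed fold-change-threshold DE calls in one
dataset with positive evidence of non-response in the other, where
non-response means either equivalence (inside the fold-change margin) at
every shared timepoint or too-low expression ("filtered"). A gene that is DE
in one mating type but merely *not significant* in the other stays
unclassified: absence of evidence is not evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normfilter import FilterResult
from .stagewise import DecisionTable

CLASSES = ("SRB", "SRP", "SRM", "nonresponsive", "unclassified")


def shared_timepoints(samples_plus: pd.DataFrame,
                      samples_minus: pd.DataFrame) -> list[int]:
    """Timepoints (minutes) at which both datasets have both conditions."""
    def _two_sided(samples: pd.DataFrame) -> set[int]:
        counts = samples.groupby("timepoint_min", observed=True)["condition"]
        return {int(t) for t, k in counts.nunique().items() if k >= 2}

    shared = sorted(_two_sided(samples_plus) & _two_sided(samples_minus))
    if not shared:
        raise ValueError("datasets share no timepoint with both conditions")
    return shared


@dataclass
class GeneClassification:
    """Per-gene class over the union of both datasets' gene universes."""

    table: pd.DataFrame           # gene_id, gene_class, discovery_timepoint,
                                  # lfc_log2_plus, lfc_log2_minus,
                                  # other_side_status
    evidence: pd.DataFrame        # long: gene_id, dataset, timepoint, call
    shared: list[int]

    def counts(self) -> pd.Series:
        return (self.table["gene_class"].value_counts()
                .reindex(CLASSES, fill_value=0))

    def genes_in(self, cls: str) -> list[str]:
        return list(self.table.loc[self.table["gene_class"] == cls, "gene_id"])


def _side_arrays(universe: list[str], dec: DecisionTable, filt: FilterResult,
                 shared: list[int]) -> dict:
    """Boolean evidence arrays over the universe for one dataset."""
    tested_ids = set(dec.confirmed.index)
    tested = np.array([g in tested_ids for g in universe])
    conf = np.nan_to_num(dec.confirmed.reindex(universe)[shared]
                         .to_numpy(dtype=float), nan=0.0).astype(bool)
    eq = np.nan_to_num(dec.equivalent.reindex(universe)[shared]
                       .to_numpy(dtype=float), nan=0.0).astype(bool)
    # a gene absent from this dataset (or filtered) counts as filtered here
    return {
        "tested": tested,
        "filtered": ~tested,
        "resp": conf.any(axis=1),
        "conf": conf,
        "eq": eq,
        "equiv_all": eq.all(axis=1) & tested,
    }


def _first_true_timepoint(mask: np.ndarray, shared: list[int]) -> np.ndarray:
    """Earliest shared timepoint (minutes) with a True entry; -1 if none."""
    any_true = mask.any(axis=1)
    first = np.argmax(mask, axis=1)
    tps = np.asarray(shared)
    return np.where(any_true, tps[first], -1)


def classify_genes(dec_plus: DecisionTable, dec_minus: DecisionTable,
                   filt_plus: FilterResult, filt_minus: FilterResult,
                   shared: list[int],
                   lfc_plus: pd.DataFrame | None = None,
                   lfc_minus: pd.DataFrame | None = None,
                   require_equivalence: bool = True,
                   equivalence_mode: str = "all_shared_timepoints",
                   build_evidence: bool = True) -> GeneClassification:
    """Partition genes into SRB / SRP / SRM / nonresponsive / unclassified.

    ``lfc_plus`` / ``lfc_minus`` are optional genes x timepoints log2
    fold-change frames used only for reporting. ``require_equivalence=False``
    weakens specificity to "no confirmed DE" in the other dataset (no positive
    equivalence evidence required) — kept as a switch to demonstrate why the
    equivalence step matters; the default is the full workflow.
    ``equivalence_mode`` decides whether specificity demands equivalence at
    every shared timepoint (default) or only at the timepoints where the
    responsive dataset's DE was confirmed (``"de_timepoints_only"``).
    """
    shared = [int(t) for t in shared]
    universe = sorted(
        set(filt_plus.kept) | set(filt_plus.filtered)
        | set(filt_minus.kept) | set(filt_minus.filtered)
    )
    if not universe:
        raise ValueError("empty gene universe")
    sp = _side_arrays(universe, dec_plus, filt_plus, shared)
    sm = _side_arrays(universe, dec_minus, filt_minus, shared)

    if not require_equivalence:
        other_ok_p = sp["filtered"] | ~sp["resp"]
        other_ok_m = sm["filtered"] | ~sm["resp"]
    elif equivalence_mode == "all_shared_timepoints":
        other_ok_p = sp["filtered"] | sp["equiv_all"]
        other_ok_m = sm["filtered"] | sm["equiv_all"]
    elif equivalence_mode == "de_timepoints_only":
        # equivalence required only at the discovering side's confirmed tps
        other_ok_p = sp["filtered"] | (
            sp["tested"] & ~(sm["conf"] & ~sp["eq"]).any(axis=1))
        other_ok_m = sm["filtered"] | (
            sm["tested"] & ~(sp["conf"] & ~sm["eq"]).any(axis=1))
    else:
        raise ValueError(f"unknown equivalence_mode {equivalence_mode!r}")
    # the nonresponsive class always demands the strict evidence
    nonresp_p = sp["filtered"] | sp["equiv_all"]
    nonresp_m = sm["filtered"] | sm["equiv_all"]
    if not require_equivalence:
        nonresp_p = other_ok_p
        nonresp_m = other_ok_m

    is_srb = sp["resp"] & sm["resp"]
    is_srp = sp["resp"] & ~sm["resp"] & other_ok_m
    is_srm = sm["resp"] & ~sp["resp"] & other_ok_p
    is_nonresp = (~sp["resp"] & ~sm["resp"] & nonresp_p & nonresp_m)
    gene_class = np.select(
        [is_srb, is_srp, is_srm, is_nonresp],
        ["SRB", "SRP", "SRM", "nonresponsive"],
        default="unclassified",
    )

    disc_both = _first_true_timepoint(sp["conf"] | sm["conf"], shared)
    disc_p = _first_true_timepoint(sp["conf"], shared)
    disc_m = _first_true_timepoint(sm["conf"], shared)
    discovery = np.select([is_srb, is_srp, is_srm],
                          [disc_both, disc_p, disc_m], default=-1)

    other_status = np.select(
        [is_srb,
         is_srp & sm["filtered"], is_srp,
         is_srm & sp["filtered"], is_srm,
         is_nonresp],
        ["responsive", "filtered", "equivalent",
         "filtered", "equivalent", "equivalent"],
        default="inconclusive",
    )

    def _lfc_at(lfc: pd.DataFrame | None, disc: np.ndarray) -> np.ndarray:
        if lfc is None:
            return np.full(len(universe), np.nan)
        cols = [t for t in shared if t in lfc.columns]
        mat = lfc.reindex(universe)[cols].to_numpy(dtype=float)
        tps = np.asarray(cols)
        out = np.full(len(universe), np.nan)
        for j, t in enumerate(tps):
            sel = disc == t
            out[sel] = mat[sel, j]
        return out

    table = pd.DataFrame({
        "gene_id": universe,
        "gene_class": gene_class,
        "discovery_timepoint": np.where(discovery >= 0, discovery, np.nan),
        "lfc_log2_plus": _lfc_at(lfc_plus, discovery),
        "lfc_log2_minus": _lfc_at(lfc_minus, discovery),
        "other_side_status": other_status,
    })
    assert table["gene_class"].isin(CLASSES).all()
    # mutual exclusivity is structural with np.select; assert anyway
    assert not np.any(is_srb & (is_srp | is_srm))

    if build_evidence:
        ev = []
        for name, side in (("MTplus", sp), ("MTminus", sm)):
            filt_idx = np.where(side["filtered"])[0]
            ev.append(pd.DataFrame({
                "gene_id": np.asarray(universe)[filt_idx],
                "dataset": name, "timepoint": -1, "call": "filtered"}))
            tested_idx = np.where(side["tested"])[0]
            for j, t in enumerate(shared):
                call = np.where(side["conf"][tested_idx, j], "de_confirmed",
                                np.where(side["equiv_all"][tested_idx],
                                         "equivalent", "inconclusive"))
                ev.append(pd.DataFrame({
                    "gene_id": np.asarray(universe)[tested_idx],
                    "dataset": name, "timepoint": t, "call": call}))
        evidence = pd.concat(ev, ignore_index=True)
    else:
        evidence = pd.DataFrame(columns=["gene_id", "dataset", "timepoint",
                                         "call"])
    return GeneClassification(table=table, evidence=evidence,
                              shared=list(shared))


def classification_report(cls: GeneClassification) -> dict:
    """Counts per class, per-timepoint breakdown and discovery directions."""
    table = cls.table
    counts = cls.counts()
    key = table[table["gene_class"].isin(["SRB", "SRP", "SRM"])].copy()
    by_tp = key.groupby(["gene_class", "discovery_timepoint"]).size()

    def _direction(row) -> str:
        lfc = (row["lfc_log2_minus"] if row["gene_class"] == "SRM"
               else row["lfc_log2_plus"])
        if lfc is None or not np.isfinite(lfc):
            return "unknown"
        return "up" if lfc > 0 else "down"

    if len(key):
        key["direction"] = key.apply(_direction, axis=1)
        directions = key.groupby(["gene_class", "direction"]).size()
    else:
        directions = pd.Series(dtype=int)
    total = int(counts.sum())
    assert total == len(table)
    return {
        "counts": counts,
        "by_timepoint": by_tp,
        "directions": directions,
        "n_universe": total,
    }
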