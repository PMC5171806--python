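"""Condition-specific TSS usage: substrate-specific sets, primary-TSS
switching, fold-change filtering, and association with differential
expression."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_classify import ClassifiedTss
from .tss_calling import Tss


def expression_matrix(tss_list: list[Tss], conditions: list[str] | None = None
                      ) -> pd.DataFrame:
    """Mean-RPM matrix: rows indexed by ``strand:position``, one column per
    condition."""
    if conditions is None:
        seen: list[str] = []
        for t in tss_list:
            for c in t.mean_rpm_by_condition:
                if c not in seen:
                    seen.append(c)
        conditions = seen
    rows = {f"{t.strand}:{t.position}":
            [t.mean_rpm_by_condition.get(c, 0.0) for c in conditions]
            for t in sorted(tss_list, key=lambda t: (t.strand, t.position))}
    return pd.DataFrame.from_dict(rows, orient="index", columns=conditions)


def substrate_specific_tss(tss_list: list[Tss], condition: str,
                           mode: str = "strict", reference: str | None = None
                           ) -> list[Tss]:
    """TSS detected only on one carbon source.

    ``strict`` mode returns TSS whose detected-condition set is exactly
    ``{condition}``. ``vs_reference`` mode returns TSS detected on
    ``condition`` but not on the reference substrate (typically glucose),
    regardless of other conditions.
    """
    known = set()
    for t in tss_list:
        known |= set(t.mean_rpm_by_condition) | t.detected_conditions
    if condition not in known:
        raise ValueError(f"unknown condition {condition!r}; have {sorted(known)}")
    if mode == "strict":
        return [t for t in tss_list if t.detected_conditions == {condition}]
    if mode == "vs_reference":
        if reference is None:
            raise ValueError("vs_reference mode needs a reference condition")
        if reference not in known:
            raise ValueError(f"unknown reference condition {reference!r}")
        return [t for t in tss_list
                if condition in t.detected_conditions
                and reference not in t.detected_conditions]
    raise ValueError(f"unknown mode {mode!r}")


def primary_switching(classified: list[ClassifiedTss]
                      ) -> tuple[list[tuple[str, dict[str, int]]], int]:
    """Genes whose per-condition primary TSS position changes with condition.

    Requires per-condition primaries (``assign_primary(mode="per_condition")``).
    Returns the switching genes with their condition-to-primary-position map,
    and the denominator: the number of genes with at least one InterS TSS.
    """
    gene_primary: dict[str, dict[str, int]] = {}
    genes_with_inters: set[str] = set()
    for c in classified:
        if c.tss_class != "InterS" or c.gene_id == "none":
            continue
        genes_with_inters.add(c.gene_id)
        for cond in c.primary_conditions:
            gene_primary.setdefault(c.gene_id, {})[cond] = c.tss.position
    switchers = []
    for gene_id in sorted(gene_primary):
        positions = gene_primary[gene_id]
        if len(set(positions.values())) > 1:
            switchers.append((gene_id, dict(sorted(positions.items()))))
    return switchers, len(genes_with_inters)


def fold_change_filter(matrix: pd.DataFrame, min_fold: float = 30.0,
                       floor_rpm: float = 0.0) -> pd.DataFrame:
    """Keep TSS with at least a ``min_fold`` expression change between some
    pair of conditions.

    The fold change of a row is max(rpm + floor) / min(rpm + floor) over its
    condition columns; "at least" is inclusive. With ``floor_rpm == 0`` a
    zero minimum counts as an infinite fold change whenever the maximum is
    positive, so sites silent on one substrate pass.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    if floor_rpm < 0:
        raise ValueError("floor_rpm must be >= 0")
    if matrix.empty:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float) + floor_rpm
    hi = values.max(axis=1)
    lo = values.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 0.0))
    return matrix.loc[fold >= min_fold]


def chisq_association(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, df=1,
    without continuity correction.

    ``table`` is [[a, b], [c, d]]: rows split genes by substrate-specific-TSS
    status, columns by differential-expression status.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if arr.sum() <= 0:
        raise ValueError("degenerate table: total count is 0")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column sum is 0")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def de_association_table(classified: list[ClassifiedTss],
                         specific_tss_keys: set[tuple[str, int]],
                         de_genes: set[str],
                         universe: set[str]) -> list[list[int]]:
    """Build the 2x2 gene table: substrate-specific InterS TSS (yes/no) vs
    differentially expressed (yes/no), over a gene universe."""
    specific_genes = {c.gene_id for c in classified
                      if c.tss_class == "InterS" and c.gene_id != "none"
                      and (c.tss.strand, c.tss.position) in specific_tss_keys}
    a = len(specific_genes & de_genes)
    b = len(specific_genes - de_genes)
    c = len((universe - specific_genes) & de_genes)
    d = len(universe - specific_genes - de_genes)
    return [[a, b], [c, d]]
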