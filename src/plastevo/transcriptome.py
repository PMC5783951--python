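"""Turn experimental-evolution expression matrices into o/p/a triplets.

Datasets arrive as genes x samples matrices (FPKM, normalized counts — any
non-negative per-study scale) with per-sample stage / line / case labels.
The pipeline filters genes with missing values, equalizes the grand mean
across datasets, averages replicates within lines, and assembles one
(L_o, L_p, L_a) table per adaptation case from a manifest. Classification at
a cutoff proportional to L_o is invariant to the per-dataset rescaling, so
the normalization target is a free choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("o", "p", "a")


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with per-sample stage labels.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with at least a ``stage``
    column (o|p|a); ``line`` and other grouping columns are optional.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    name: str = "dataset"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        bad = set(self.samples["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.samples.copy(), self.name)


def filter_missing(
    ds: ExpressionDataset, sentinels: tuple = ()
) -> ExpressionDataset:
    """Drop genes with any missing expression value.

    ``sentinels`` lists additional values to treat as missing (e.g. a
    negative placeholder used by some array pipelines) besides NaN/empty.
    """
    values = ds.values.apply(pd.to_numeric, errors="coerce")
    for s in sentinels:
        values = values.mask(values == s)
    keep = values.notna().all(axis=1)
    if not keep.any():
        raise ValueError(f"all genes dropped from {ds.name!r}")
    n_dropped = int((~keep).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "%s: dropped %d genes with missing values", ds.name, n_dropped
        )
    return ExpressionDataset(values[keep], ds.samples, ds.name)


def normalize_mean(
    datasets: list[ExpressionDataset], target: float = 1.0
) -> list[ExpressionDataset]:
    """Rescale each dataset by one scalar so its grand mean equals *target*.

    Within-dataset ratios (and hence all classifications at cutoffs
    proportional to L_o) are unchanged.
    """
    out = []
    for ds in datasets:
        grand = float(ds.values.to_numpy().mean())
        if grand == 0:
            raise ValueError(f"dataset {ds.name!r} has zero mean expression")
        out.append(
            ExpressionDataset(ds.values * (target / grand), ds.samples, ds.name)
        )
    return out


def average_replicates(
    ds: ExpressionDataset, grouping: list[str] | None = None
) -> ExpressionDataset:
    """Arithmetic mean per gene within each sample group.

    *grouping* names columns of ``ds.samples`` (default ``["stage", "line"]``
    where present); the result has one pseudo-sample per group, labelled by
    the joined group key.
    """
    if grouping is None:
        grouping = [c for c in ("stage", "line") if c in ds.samples.columns]
    for g in grouping:
        if g not in ds.samples.columns:
            raise KeyError(f"grouping column {g!r} not in sample labels")

    groups = ds.samples.groupby(grouping, sort=False, dropna=False)
    new_cols = {}
    new_meta = []
    for key, members in groups:
        key_t = key if isinstance(key, tuple) else (key,)
        sid = "|".join(str(k) for k in key_t)
        cols = [c for c in members.index if c in ds.values.columns]
        if not cols:
            raise ValueError(f"empty sample group {sid!r}")
        new_cols[sid] = ds.values[cols].mean(axis=1)
        meta = {g: k for g, k in zip(grouping, key_t)}
        meta["n_replicates"] = len(cols)
        new_meta.append(pd.Series(meta, name=sid))
    values = pd.DataFrame(new_cols, index=ds.values.index)
    samples = pd.DataFrame(new_meta)
    return ExpressionDataset(values, samples, ds.name)


# ---------------------------------------------------------------------- #
@dataclass
class CaseManifest:
    """Mapping from samples to adaptation cases.

    ``cases`` maps a case id to a dict with keys 'o', 'p', 'a', each listing
    the sample ids whose mean estimates that stage's expression profile
    (replicate-specific stage-a samples may share stage-o/p samples across
    cases).
    """

    cases: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, stages in self.cases.items():
            for st in STAGES:
                if st not in stages or not stages[st]:
                    raise ValueError(f"case {cid!r} is missing stage {st!r} samples")

    @classmethod
    def from_yaml(cls, path) -> "CaseManifest":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(cases=payload["cases"])


def build_triplets(
    ds: ExpressionDataset, manifest: CaseManifest
) -> dict[str, pd.DataFrame]:
    """One (trait_id, L_o, L_p, L_a) table per adaptation case."""
    out = {}
    for cid, stages in manifest.cases.items():
        cols = {}
        for st, label in zip(STAGES, ("L_o", "L_p", "L_a")):
            sample_ids = stages[st]
            absent = [s for s in sample_ids if s not in ds.values.columns]
            if absent:
                raise KeyError(
                    f"case {cid!r}, stage {st!r}: samples not in dataset: {absent}"
                )
            cols[label] = ds.values[sample_ids].mean(axis=1)
        table = pd.DataFrame(cols)
        table.insert(0, "trait_id", table.index.astype(str))
        out[cid] = table.reset_index(drop=True)
    return out


def growth_independent_mask(
    expr_by_rate: pd.DataFrame, strict: bool = False
) -> pd.Series:
    """Flag genes whose expression is not monotone across ordered growth rates.

    *expr_by_rate* has one column per growth rate, columns ordered by
    increasing rate (at least 3 required). With ``strict=False`` (default)
    ties are allowed within a monotone run, so a non-strictly monotone gene
    still counts as growth-rate-dependent.
    """
    if expr_by_rate.shape[1] < 3:
        raise ValueError("need at least 3 ordered growth-rate columns")
    x = expr_by_rate.to_numpy(dtype=float)
    d = np.diff(x, axis=1)
    if strict:
        inc = (d > 0).all(axis=1)
        dec = (d < 0).all(axis=1)
    else:
        inc = (d >= 0).all(axis=1)
        dec = (d <= 0).all(axis=1)
    return pd.Series(~(inc | dec), index=expr_by_rate.index, name="growth_independent")
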