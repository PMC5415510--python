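"""What drives a regionalization, and how much response variance it captures.

Two independent checks of a finished region set: (1) a random-forest
classifier predicting region membership from the raw standardized
variables, whose mean-decrease-in-Gini importances profile which
terrestrial / climate / freshwater variables shaped the regions; and (2) a
one-way variance decomposition of point responses (e.g. lake total
phosphorus, Secchi depth) never used in region delineation, whose
SSB/(SSW+SSB) is the among-region variance fraction the regions capture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cluster import Regionalization
from .evaluate import within_between_ss
from .io import ResponseTable, SpatialUnitTable

log = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    variable_name: list[str]
    importance: np.ndarray   # mean decrease in Gini impurity (normalized)
    oob_error: float
    n_trees: int
    region_set_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variable_name,
            "importance": self.importance,
            "oob_error": self.oob_error,
            "n_trees": self.n_trees,
            "region_set": self.region_set_id,
        })

    def ranked(self) -> pd.DataFrame:
        return self.to_frame().sort_values("importance", ascending=False)


@dataclass
class ResponsePartitionReport:
    response_name: str
    ssw: float
    ssb: float
    total_ss: float
    ratio: float             # SSW : SSB
    among_fraction: float    # SSB / total SS
    n_points: int
    k_occupied: int

    def to_dict(self) -> dict:
        return {
            "response": self.response_name, "ssw": self.ssw, "ssb": self.ssb,
            "total_ss": self.total_ss, "ratio": self.ratio,
            "among_fraction": self.among_fraction, "n_points": self.n_points,
            "k_occupied": self.k_occupied,
        }


def region_variable_importance(raw_table: SpatialUnitTable,
                               regionalization: Regionalization,
                               n_trees: int = 500, seed: int = 0,
                               region_set_id: str = "") -> ImportanceTable:
    """Gini importance of each raw variable for predicting region membership.

    Fits a seeded random forest of ``n_trees`` classification trees and
    reports per-variable mean decrease in Gini impurity plus the out-of-bag
    (OOB) classification error.  Deterministic given the seed.
    """
    if regionalization.k < 2:
        raise ValueError("variable importance needs k >= 2 regions")
    y = regionalization.labels_for(raw_table.unit_id)
    X = raw_table.values
    if np.isnan(X).any():
        raise ValueError("raw table has missing values; preprocess first")
    zero_var = X.std(axis=0) < 1e-12
    if zero_var.any():
        names = [raw_table.variable_names[j] for j in np.flatnonzero(zero_var)]
        warnings.warn(f"zero-variance variable(s) get importance 0: {names}",
                      stacklevel=2)
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", oob_score=True,
        random_state=seed % (2**31 - 1), n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny forests can miss OOB coverage for some samples; not an error here
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(X, y)
    return ImportanceTable(
        variable_name=list(raw_table.variable_names),
        importance=rf.feature_importances_,
        oob_error=1.0 - float(rf.oob_score_),
        n_trees=n_trees,
        region_set_id=region_set_id,
    )


def partition_response_variance(responses: ResponseTable,
                                regionalization: Regionalization,
                                response_name: str) -> ResponsePartitionReport:
    """One-way SSW/SSB decomposition of a point response across regions.

    Points map to regions through their containing unit; points in units
    absent from the regionalization, or with a missing response, are
    dropped (counts logged).  ``among_fraction`` = SSB / (SSW + SSB) is the
    share of response variance at the regional scale.
    """
    if response_name not in responses.response_names:
        raise KeyError(f"unknown response {response_name!r}; "
                       f"have {responses.response_names}")
    df = responses.data[["unit_id", response_name]].copy()
    unit_to_region = dict(zip(regionalization.unit_id, regionalization.label))
    df["region"] = df["unit_id"].map(unit_to_region)
    n_unmapped = int(df["region"].isna().sum())
    if n_unmapped:
        log.info("dropping %d point(s) in units outside the regionalization", n_unmapped)
    n_missing = int(df[response_name].isna().sum())
    if n_missing:
        log.info("dropping %d point(s) with missing %s", n_missing, response_name)
    df = df.dropna(subset=["region", response_name])

    if len(df) < 2:
        raise ValueError("need at least 2 points with responses")
    k_occ = df["region"].nunique()
    if k_occ < 2:
        raise ValueError("need at least 2 occupied regions")

    y = df[response_name].to_numpy(dtype=float)
    labels = df["region"].to_numpy()
    ssw, ssb, total = within_between_ss(y.reshape(-1, 1), labels)
    return ResponsePartitionReport(
        response_name=response_name, ssw=ssw, ssb=ssb, total_ss=total,
        ratio=ssw / ssb if ssb > 0 else float("inf"),
        among_fraction=ssb / total if total > 0 else 0.0,
        n_points=len(df), k_occupied=int(k_occ),
    )
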