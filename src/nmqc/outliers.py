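"""Extreme-outlier QC decisions from deviation z-scores.

A subject-by-IDP z-score matrix is thresholded at |z| > 7 (by default) to
flag candidate artefactual scans; the threshold is two-sided because
artefacts can push a phenotype in either direction, and strict at the
boundary.  NaN z-scores are refused rather than silently dropped so no
subject disappears from the QC accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OutlierTable", "flag_outliers", "outlier_frequency", "assign_categories"]

DEFAULT_THRESHOLD = 7.0
VALID_CATEGORIES = ("acquisition", "processing", "incidental", "unreviewed")


@dataclass
class OutlierTable:
    """Flag matrix plus per-subject bookkeeping.

    ``flags`` is a subjects x IDPs boolean DataFrame; ``frequency`` the
    per-subject count of flagged IDPs; ``category`` a per-subject artefact
    label, ``unreviewed`` for flagged subjects without one.
    """

    flags: pd.DataFrame
    threshold: float
    z: pd.DataFrame
    category: pd.Series = field(default=None)

    def __post_init__(self):
        if self.category is None:
            self.category = pd.Series(
                ["unreviewed"] * len(self.flags), index=self.flags.index, dtype=object
            )

    @property
    def frequency(self) -> pd.Series:
        """Per-subject count of IDPs in which the subject is an outlier."""
        return self.flags.sum(axis=1)

    @property
    def unique_outliers(self) -> pd.Index:
        """Subjects flagged in at least one IDP."""
        return self.flags.index[self.frequency >= 1]

    @property
    def multi_idp_outliers(self) -> pd.Index:
        """Subjects flagged in at least two IDPs."""
        return self.flags.index[self.frequency >= 2]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, idp_name, z, flagged, category."""
        long = self.z.stack().rename("z").reset_index()
        long.columns = ["subject_id", "idp_name", "z"]
        flags = self.flags.stack().reset_index(drop=True)
        long["flagged"] = flags.to_numpy()
        long["category"] = self.category.reindex(long["subject_id"]).to_numpy()
        return long

    def subject_summary(self) -> pd.DataFrame:
        """Per-subject summary: outlier frequency, max |z| and category."""
        return pd.DataFrame(
            {
                "frequency": self.frequency,
                "max_abs_z": self.z.abs().max(axis=1),
                "category": self.category,
            }
        )


def flag_outliers(z: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> OutlierTable:
    """Flag subject-IDP cells with |z| strictly greater than ``threshold``.

    Parameters
    ----------
    z : DataFrame
        Subjects x IDPs z-score matrix (index = subject ids).
    threshold : float
        Two-sided threshold in SD units; default 7.

    Raises
    ------
    ValueError
        If the threshold is not positive, or any z is NaN (the error names
        the first offending subject and IDP).
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    z = pd.DataFrame(z).astype(float)
    if z.isna().any().any():
        nan_mask = z.isna()
        subj = nan_mask.any(axis=1).idxmax()
        idp = nan_mask.loc[subj].idxmax()
        raise ValueError(f"NaN z-score for subject {subj!r}, IDP {idp!r}")
    flags = z.abs() > threshold
    return OutlierTable(flags=flags, threshold=float(threshold), z=z)


def outlier_frequency(table: OutlierTable):
    """Both marginals of the flag matrix.

    Returns ``(per_subject, per_idp)``: counts of flagged IDPs per subject
    and of flagged subjects per IDP.
    """
    return table.flags.sum(axis=1), table.flags.sum(axis=0)


def assign_categories(table: OutlierTable, labels) -> OutlierTable:
    """Merge per-subject artefact-category labels into the table.

    ``labels`` maps subject id -> category (from human review or synthetic
    truth).  Flagged subjects without a label stay ``unreviewed``.  Labels
    for non-flagged subjects are stored but trigger a warning.
    """
    labels = pd.Series(labels, dtype=object)
    bad = set(labels.unique()) - set(VALID_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    unknown_subjects = labels.index.difference(table.flags.index)
    if len(unknown_subjects):
        raise ValueError(f"labels for unknown subjects: {list(unknown_subjects)[:5]}")
    flagged = set(table.unique_outliers)
    extra = [s for s in labels.index if s not in flagged]
    if extra:
        logger.warning(
            "%d labelled subjects are not flagged outliers (stored anyway)", len(extra)
        )
    category = table.category.copy()
    category.loc[labels.index] = labels
    return OutlierTable(
        flags=table.flags, threshold=table.threshold, z=table.z, category=category
    )
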