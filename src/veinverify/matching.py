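"""Distance matrices and nearest-neighbour identity decisions.

Verification compares each test embedding against every enrolled
embedding under one of four dissimilarities — Euclidean, Manhattan,
cosine (1 - cos angle) and correlation (1 - Pearson r).  The genuine
mask marks same-subject pairs; genuine and impostor score lists drive the
FAR/FRR evaluation.  Identification assigns each test sample the subject
of its globally nearest enrolled sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["DistanceMatrix", "distance_matrix", "nn_identify", "METRICS"]

METRICS = ("euclidean", "manhattan", "cosine", "correlation")

_CDIST_NAME = {"euclidean": "euclidean", "manhattan": "cityblock",
               "cosine": "cosine", "correlation": "correlation"}


@dataclass
class DistanceMatrix:
    """Test x enroll dissimilarities with subject bookkeeping."""

    values: np.ndarray              # (n_test, n_enroll)
    metric: str
    test_subjects: np.ndarray
    enroll_subjects: np.ndarray
    test_samples: np.ndarray | None = None
    enroll_samples: np.ndarray | None = None

    @property
    def genuine_mask(self) -> np.ndarray:
        return self.test_subjects[:, None] == self.enroll_subjects[None, :]

    def genuine_scores(self, per_claim_min: bool = False) -> np.ndarray:
        """Same-subject scores: all pairs, or the per-claim minimum.

        ``per_claim_min`` reduces each test sample's genuine comparisons
        to the best (smallest) one, modelling a claim verified against
        the closest enrolled sample of the claimed identity.
        """
        if per_claim_min:
            masked = np.where(self.genuine_mask, self.values, np.inf)
            return masked.min(axis=1)
        return self.values[self.genuine_mask]

    def impostor_scores(self, per_claim_min: bool = False) -> np.ndarray:
        """Different-subject scores: all pairs, or per (test, wrong subject) minimum."""
        if per_claim_min:
            out = []
            for s in np.unique(self.enroll_subjects):
                cols = self.enroll_subjects == s
                rows = self.test_subjects != s
                if rows.any():
                    out.append(self.values[np.ix_(rows, cols)].min(axis=1))
            return np.concatenate(out)
        return self.values[~self.genuine_mask]


def distance_matrix(test: np.ndarray, enroll: np.ndarray, metric: str,
                    test_subjects: np.ndarray, enroll_subjects: np.ndarray,
                    test_samples: np.ndarray | None = None,
                    enroll_samples: np.ndarray | None = None) -> DistanceMatrix:
    """Dense pairwise dissimilarity matrix between test and enrolled vectors.

    Cosine/correlation entries involving a zero-norm (or constant, for
    correlation) vector are undefined; they are set to 1 with a warning.
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    enroll = np.atleast_2d(np.asarray(enroll, dtype=float))
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if test.shape[1] != enroll.shape[1]:
        raise ValueError("feature dimensions differ between test and enroll")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = cdist(test, enroll, metric=_CDIST_NAME[metric])
    bad = ~np.isfinite(values)
    if bad.any():
        warnings.warn(f"{bad.sum()} undefined {metric} distances set to 1 "
                      "(zero-norm or constant vector)")
        values[bad] = 1.0
    return DistanceMatrix(values=values, metric=metric,
                          test_subjects=np.asarray(test_subjects),
                          enroll_subjects=np.asarray(enroll_subjects),
                          test_samples=test_samples, enroll_samples=enroll_samples)


def nn_identify(d: DistanceMatrix) -> np.ndarray:
    """Predicted subject per test sample: subject of the nearest gallery vector.

    Ties are broken by lowest subject id, then lowest sample index, so
    the decision is deterministic.
    """
    if d.values.size == 0:
        raise ValueError("empty gallery")
    n_enroll = d.values.shape[1]
    samples = d.enroll_samples if d.enroll_samples is not None else np.arange(n_enroll)
    order = np.lexsort((samples, d.enroll_subjects))
    winners = np.argmin(d.values[:, order], axis=1)     # argmin takes first minimum
    return d.enroll_subjects[order][winners]
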