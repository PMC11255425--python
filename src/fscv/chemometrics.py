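"""Principal component regression (PCR) chemometrics for voltammograms.

Background-corrected cyclic voltammograms are linear superpositions of analyte
signatures (dopamine oxidation/reduction features, pH-shift signatures) plus
noise.  PCR separates them: labeled reference voltammograms are mean-centered
and decomposed by SVD, the leading principal components are retained, and a
least-squares map from component scores to known analyte magnitudes is fit.
Unknown scans are projected onto the retained components to estimate dopamine
while rejecting pH/drift interferents; the squared norm of the unprojected
residual (the Q statistic) flags scans the training space cannot explain.

The standard training set holds ten references: five dopamine, three acidic-pH
and two basic-pH voltammograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "TrainingSet",
    "PCRModel",
    "PCRPrediction",
    "fit_pcr",
    "predict_da",
    "save_model",
    "load_model",
]

ANALYTES = ("DA", "acidic_pH", "basic_pH")


@dataclass
class TrainingSet:
    """Labeled reference voltammograms.

    ``spectra`` — (n_refs, samples_per_scan) currents in nA, already passed
    through the same preprocessing as measurement scans.
    ``analytes`` — per-row identity from :data:`ANALYTES`.
    ``magnitudes`` — signed magnitude per row: dopamine amplitude (in the
    units given by ``units``, typically the oxidation-peak current in nA) for
    DA rows; pH shift in pH units for pH rows (negative = acidic).
    """

    spectra: np.ndarray
    analytes: "list[str]"
    magnitudes: np.ndarray
    units: str = "nA"

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if len(self.analytes) != self.spectra.shape[0]:
            raise ValueError("one analyte label per spectrum row required")
        if self.magnitudes.shape[0] != self.spectra.shape[0]:
            raise ValueError("one magnitude per spectrum row required")
        unknown = set(self.analytes) - set(ANALYTES)
        if unknown:
            raise ValueError(f"unknown analyte labels: {sorted(unknown)}")

    @property
    def n_refs(self) -> int:
        return self.spectra.shape[0]

    def composition(self) -> "dict[str, int]":
        return {a: self.analytes.count(a) for a in ANALYTES}

    def label_matrix(self) -> np.ndarray:
        """(n_refs, 2) response matrix: column 0 = DA magnitude, column 1 =
        signed pH shift (acidic rows forced negative, basic positive)."""
        y = np.zeros((self.n_refs, 2))
        for i, (a, m) in enumerate(zip(self.analytes, self.magnitudes)):
            if a == "DA":
                y[i, 0] = m
            elif a == "acidic_pH":
                y[i, 1] = -abs(m)
            else:
                y[i, 1] = abs(m)
        return y

    def to_csv(self, spectra_path: "str | Path", labels_path: "str | Path") -> None:
        np.savetxt(spectra_path, self.spectra, delimiter=",")
        pd.DataFrame(
            {"analyte": self.analytes, "magnitude": self.magnitudes,
             "units": [self.units] * self.n_refs}
        ).to_csv(labels_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path: "str | Path", labels_path: "str | Path") -> "TrainingSet":
        spectra = np.loadtxt(spectra_path, delimiter=",")
        labels = pd.read_csv(labels_path)
        return cls(
            spectra=spectra,
            analytes=list(labels["analyte"]),
            magnitudes=labels["magnitude"].to_numpy(),
            units=str(labels["units"].iloc[0]) if "units" in labels else "nA",
        )


@dataclass
class PCRModel:
    """Trained chemometric model.

    ``components`` is (k, samples_per_scan) with orthonormal rows;
    ``regression`` maps k-dimensional scores to centered (DA, pH) responses,
    with ``label_mean`` added back at prediction time.  ``q_threshold`` is the
    residual limit above which a scan is flagged as unexplained by the
    training space.
    """

    mean_spectrum: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray
    regression: np.ndarray
    label_mean: np.ndarray
    q_threshold: float
    units: str = "nA"
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return self.components.shape[0]


@dataclass
class PCRPrediction:
    """Per-scan dopamine estimates with residual diagnostics."""

    da: np.ndarray
    ph: np.ndarray
    q: np.ndarray
    flagged: np.ndarray

    @property
    def frac_flagged(self) -> float:
        return float(np.mean(self.flagged)) if self.flagged.size else 0.0


def fit_pcr(
    training: TrainingSet,
    variance_keep: float = 0.995,
    q_quantile: float = 0.95,
    q_floor_rel: float = 1e-8,
) -> PCRModel:
    """Fit a PCR model to a labeled reference set.

    The reference matrix is mean-centered and decomposed by SVD; the smallest
    number of components whose cumulative explained variance reaches
    ``variance_keep`` is retained (capped at n_refs − 1 and at the numerical
    rank).  Scores of the training spectra are regressed onto the centered
    label matrix by least squares.  The Q threshold is the ``q_quantile``
    quantile of the training residuals, floored at ``q_floor_rel`` times the
    mean squared spectrum norm so noiseless reference sets do not produce a
    degenerate zero threshold.
    """
    if training.n_refs < 3:
        raise ValueError("need at least 3 reference spectra")
    if "DA" not in training.analytes:
        raise ValueError("training set must contain at least one DA reference")

    x = training.spectra
    mean = x.mean(axis=0)
    xc = x - mean
    total_var = float(np.sum(xc**2))
    if total_var <= 0:
        raise ValueError("degenerate training matrix: zero variance")

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var_ratio = s**2 / np.sum(s**2)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
    k = int(np.searchsorted(np.cumsum(var_ratio), variance_keep) + 1)
    k = min(k, training.n_refs - 1, rank)

    components = vt[:k]
    scores = xc @ components.T
    y = training.label_matrix()
    y_mean = y.mean(axis=0)
    regression, *_ = np.linalg.lstsq(scores, y - y_mean, rcond=None)

    resid = xc - scores @ components
    q_train = np.sum(resid**2, axis=1)
    q_floor = q_floor_rel * float(np.mean(np.sum(xc**2, axis=1)))
    q_threshold = max(float(np.quantile(q_train, q_quantile)), q_floor)

    return PCRModel(
        mean_spectrum=mean,
        components=components,
        singular_values=s[:k],
        regression=regression,
        label_mean=y_mean,
        q_threshold=q_threshold,
        units=training.units,
        explained_variance_ratio=var_ratio[:k],
    )


def predict_da(model: PCRModel, scans: np.ndarray) -> PCRPrediction:
    """Estimate dopamine (and pH shift) for each scan of a preprocessed stream.

    Each scan is centered with the training mean, projected onto the retained
    components, and mapped through the regression; Q is the squared norm of
    the part of the centered scan outside the component span.  Scans with
    Q above the model threshold are flagged but their values are retained.
    """
    scans = np.atleast_2d(np.asarray(scans, dtype=float))
    if scans.shape[1] != model.mean_spectrum.shape[0]:
        raise ValueError(
            f"scan length {scans.shape[1]} does not match model spectra length "
            f"{model.mean_spectrum.shape[0]}"
        )
    xc = scans - model.mean_spectrum
    scores = xc @ model.components.T
    pred = scores @ model.regression + model.label_mean
    resid = xc - scores @ model.components
    q = np.sum(resid**2, axis=1)
    return PCRPrediction(
        da=pred[:, 0],
        ph=pred[:, 1],
        q=q,
        flagged=q > model.q_threshold,
    )


def save_model(model: PCRModel, path: "str | Path") -> None:
    """Serialize a PCR model to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("pcr")
        for name in (
            "mean_spectrum", "components", "singular_values",
            "regression", "label_mean", "explained_variance_ratio",
        ):
            g.create_dataset(name, data=getattr(model, name))
        g.attrs["q_threshold"] = model.q_threshold
        g.attrs["units"] = model.units


def load_model(path: "str | Path") -> PCRModel:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["pcr"]
        return PCRModel(
            mean_spectrum=g["mean_spectrum"][()],
            components=g["components"][()],
            singular_values=g["singular_values"][()],
            regression=g["regression"][()],
            label_mean=g["label_mean"][()],
            q_threshold=float(g.attrs["q_threshold"]),
            units=str(g.attrs["units"]),
            explained_variance_ratio=g["explained_variance_ratio"][()],
        )
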