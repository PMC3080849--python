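"""Principal component analysis of coordinate ensembles.

A reference structure set (e.g. the public X-ray structures of a
two-domain protein in its open and closed forms) defines a basis of
collective motions; trajectories are then projected onto the leading
components.  For hinge-bending proteins the first one or two components
capture the domain closure and dominate the variance.

The estimator follows the fit/transform idiom: superposition of every
frame onto an iteratively refined mean structure, population-normalised
(divide-by-N) covariance of the flattened coordinates, eigendecomposition,
and a deterministic sign convention (largest-magnitude loading positive).
"""

from __future__ import annotations

import json

import numpy as np

from .ensemble import ConformerEnsemble
from .geometry import kabsch_superpose


def _frames_array(ensemble) -> np.ndarray:
    if isinstance(ensemble, ConformerEnsemble):
        return ensemble.coords
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected (n_frames, n_atoms, 3) coordinates")
    return arr


class EnsemblePCA:
    """PCA over superposed coordinate frames.

    Parameters
    ----------
    superpose : bool
        Rigid-body superposition of each frame onto the running mean
        structure before covariance (2 refinement iterations by default),
        which removes dependence on the arbitrary global orientation of
        the inputs.
    n_iter_mean : int
        Mean-structure refinement iterations.

    Attributes (after fit)
    ----------------------
    mean_ : (3N,) flattened mean structure (Å)
    components_ : (3N, 3N) orthonormal eigenvectors, rows ordered by
        decreasing eigenvalue
    explained_variance_ : eigenvalues (Å²), non-increasing
    explained_variance_ratio_ : per-component variance fractions
    """

    def __init__(self, superpose: bool = True, n_iter_mean: int = 2):
        self.superpose = superpose
        self.n_iter_mean = n_iter_mean

    # -- estimator API ----------------------------------------------------
    def fit(self, ensemble) -> "EnsemblePCA":
        frames = _frames_array(ensemble).copy()
        n_frames, n_atoms, _ = frames.shape
        if n_frames < 2:
            raise ValueError("PCA needs at least 2 reference frames")
        if self.superpose:
            reference = frames[0]
            for _ in range(max(1, self.n_iter_mean)):
                aligned = np.array([
                    kabsch_superpose(f, reference)[3] for f in frames])
                reference = aligned.mean(axis=0)
                frames = aligned
        flat = frames.reshape(n_frames, 3 * n_atoms)
        self.mean_ = flat.mean(axis=0)
        centered = flat - self.mean_
        cov = centered.T @ centered / n_frames  # population normalisation
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order].T
        # deterministic sign: largest-|loading| positive
        for row in evecs:
            j = np.argmax(np.abs(row))
            if row[j] < 0:
                row *= -1.0
        self.components_ = evecs
        self.explained_variance_ = evals
        total = evals.sum()
        self.explained_variance_ratio_ = (evals / total if total > 0
                                          else np.zeros_like(evals))
        self.n_atoms_ = n_atoms
        return self

    def transform(self, ensemble, n_components: int | None = None) -> np.ndarray:
        """Component scores for each frame (superposed onto the fit mean)."""
        if not hasattr(self, "components_"):
            raise RuntimeError("fit the basis before projecting")
        frames = _frames_array(ensemble)
        if frames.shape[1] != self.n_atoms_:
            raise ValueError(
                f"atom count {frames.shape[1]} does not match basis "
                f"({self.n_atoms_})")
        k = len(self.components_) if n_components is None else int(n_components)
        mean_struct = self.mean_.reshape(self.n_atoms_, 3)
        scores = np.empty((frames.shape[0], k))
        for i, f in enumerate(frames):
            aligned = kabsch_superpose(f, mean_struct)[3] if self.superpose else f
            scores[i] = self.components_[:k] @ (aligned.ravel() - self.mean_)
        return scores

    def fit_transform(self, ensemble, n_components=None) -> np.ndarray:
        return self.fit(ensemble).transform(ensemble, n_components)

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct frames from scores (all-components → lossless)."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        k = scores.shape[1]
        flat = scores @ self.components_[:k] + self.mean_
        return flat.reshape(len(scores), self.n_atoms_, 3)

    # -- persistence ------------------------------------------------------
    def to_json(self, path, n_components: int | None = None) -> None:
        k = (len(self.components_) if n_components is None
             else int(n_components))
        with open(path, "w") as fh:
            json.dump({
                "mean": self.mean_.tolist(),
                "eigenvalues": self.explained_variance_[:k].tolist(),
                "eigenvectors": self.components_[:k].tolist(),
                "superpose": self.superpose,
            }, fh)

    @classmethod
    def from_json(cls, path) -> "EnsemblePCA":
        with open(path) as fh:
            d = json.load(fh)
        obj = cls(superpose=d.get("superpose", True))
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.components_ = np.asarray(d["eigenvectors"], dtype=float)
        obj.explained_variance_ = np.asarray(d["eigenvalues"], dtype=float)
        total = obj.explained_variance_.sum()
        obj.explained_variance_ratio_ = (obj.explained_variance_ / total
                                         if total > 0
                                         else np.zeros_like(obj.explained_variance_))
        obj.n_atoms_ = len(obj.mean_) // 3
        return obj


def build_pca(ensemble, superpose: bool = True) -> EnsemblePCA:
    """Functional wrapper over :class:`EnsemblePCA.fit`."""
    return EnsemblePCA(superpose=superpose).fit(ensemble)


def project(basis: EnsemblePCA, ensemble, n_components: int = 2) -> np.ndarray:
    """Functional wrapper over :class:`EnsemblePCA.transform`."""
    return basis.transform(ensemble, n_components)
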