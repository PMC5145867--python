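"""PCA with supplementary-variable projection and hierarchical clustering.

The PCA standardises columns (centre, divide by the population standard
deviation) and diagonalises the resulting correlation matrix.  Variable
loadings are scaled to the square root of the eigenvalue, so that each
loading equals the correlation of the variable with the component scores
and lives on the correlation circle.  Supplementary (inactive) variables
are projected as plain correlations with the scores.  Clustering is
complete-linkage agglomeration on the leading component scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

__all__ = ["PcaResult", "pca", "project_supplementary", "hcluster",
           "dendrogram_newick", "skew_transform"]

#: reporting transforms for skewed parameter distributions
SKEW_TRANSFORMS = {"nuM": "log10", "lp1": "log10", "lx": "log10",
                   "lx1": "log10", "rxp": "reciprocal"}


def skew_transform(table, transforms: Optional[dict] = None):
    """Optional normality corrections for reporting: log10 or reciprocal.

    Operates on a pandas DataFrame; columns not named in ``transforms``
    (default :data:`SKEW_TRANSFORMS`) pass through unchanged, transformed
    columns are renamed ``log10_<name>`` / ``inv_<name>``.
    """
    transforms = SKEW_TRANSFORMS if transforms is None else transforms
    out = table.copy()
    for name, kind in transforms.items():
        if name not in out.columns:
            continue
        if kind == "log10":
            out[name] = np.log10(out[name])
            out = out.rename(columns={name: f"log10_{name}"})
        elif kind == "reciprocal":
            out[name] = 1.0 / out[name]
            out = out.rename(columns={name: f"inv_{name}"})
        else:
            raise ValueError(f"unknown transform {kind!r} for {name}")
    return out


@dataclass
class PcaResult:
    scores: np.ndarray          # individuals x components
    loadings: np.ndarray        # variables x components, norm sqrt(eigenvalue)
    eigenvalues: np.ndarray
    explained: np.ndarray       # fraction of variance per component
    means: np.ndarray
    sds: np.ndarray
    columns: Optional[list[str]] = None

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def standardized(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.means) / self.sds


def pca(matrix, columns: Optional[Sequence[str]] = None) -> PcaResult:
    """Correlation-matrix PCA of an individuals-by-variables matrix.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the result deterministic.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two columns")
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite values")
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    zero = np.where(sds == 0)[0]
    if zero.size:
        names = ([columns[i] for i in zero] if columns is not None
                 else zero.tolist())
        raise ValueError(f"zero-variance columns: {names}")
    z = (x - means) / sds
    corr = z.T @ z / z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = z @ eigvec
    loadings = eigvec * np.sqrt(eigval)
    explained = eigval / eigval.sum()
    return PcaResult(scores=scores, loadings=loadings, eigenvalues=eigval,
                     explained=explained, means=means, sds=sds,
                     columns=list(columns) if columns is not None else None)


def project_supplementary(result: PcaResult, supp_matrix) -> np.ndarray:
    """Correlation-circle coordinates of supplementary variables.

    Coordinate of variable v on component k is corr(v, scores_k), in
    [-1, 1].  Zero-variance variables get coordinate 0 with a warning.
    """
    v = np.asarray(supp_matrix, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] != result.scores.shape[0]:
        raise ValueError("supplementary variables must cover the same individuals")
    coords = np.zeros((v.shape[1], result.n_components))
    for j in range(v.shape[1]):
        col = v[:, j]
        sd = col.std()
        if sd == 0:
            warnings.warn(f"supplementary variable {j} has zero variance; "
                          "coordinates set to 0", stacklevel=2)
            continue
        zc = (col - col.mean()) / sd
        for k in range(result.n_components):
            sk = result.scores[:, k]
            ssd = sk.std()
            if ssd > 0:
                coords[j, k] = float(np.mean(zc * (sk - sk.mean()) / ssd))
    return coords


def hcluster(scores, k: int, n_components: int = 3) -> np.ndarray:
    """Complete-linkage clustering of the leading PCA scores; labels 1..k."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be 2-D")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of individuals {x.shape[0]}")
    sub = x[:, :min(n_components, x.shape[1])]
    link = hierarchy.linkage(sub, method="complete", metric="euclidean")
    return hierarchy.fcluster(link, t=k, criterion="maxclust")


def linkage_matrix(scores, n_components: int = 3) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    return hierarchy.linkage(x[:, :min(n_components, x.shape[1])],
                             method="complete", metric="euclidean")


def dendrogram_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Newick-style nesting of a scipy linkage matrix, with branch heights."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left = walk(node.get_left())
        right = walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return walk(tree) + ";"
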