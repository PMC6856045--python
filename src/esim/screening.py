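"""Library screening, enrichment statistics, and imprint indexing.

A screen aligns every library ensemble against the query's observer set in
a chosen search mode, assigns each molecule its best pose score, and ranks.
Enrichment is summarized as the ROC area separating actives from decoys
(Mann-Whitney statistic; ties get half credit).  Imprint indexing is the
ultra-fast baseline: each molecule is reduced to a 20-vector of maximal
similarities against a fixed basis panel and ranked by Euclidean distance to
the query's imprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .alignment import Pose, SearchMode, align
from .chem import ConformerEnsemble, Molecule
from .observers import ObserverSet
from .params import DEFAULT_PARAMS, SimParams

log = logging.getLogger(__name__)

IMPRINT_DIMENSION = 20


@dataclass
class ScreenResult:
    """Ranked screen output: per-molecule best scores and, when labels are
    known, the ROC area."""

    table: pd.DataFrame  # columns: name, score, rank, label (optional)
    poses: list[Optional[Pose]] = field(repr=False, default_factory=list)
    auc: Optional[float] = None


def screen(library: Sequence[ConformerEnsemble], obs: ObserverSet,
           mode: str | SearchMode = "pscreen",
           params: Optional[SimParams] = None,
           labels: Optional[Sequence[int]] = None) -> ScreenResult:
    """Screen a library of conformer ensembles against an observer set.

    Per-molecule failures are logged and scored as -inf; they never abort
    the screen.  Ranks are by descending score with ties broken by stable
    input order.
    """
    p = params if params is not None else DEFAULT_PARAMS
    names, scores, best_poses = [], [], []
    for ens in library:
        names.append(ens.molecule.name)
        try:
            poses = align(ens, obs, mode=mode, top_n=1, params=p)
            if not poses:
                raise RuntimeError("no poses produced")
            scores.append(poses[0].score)
            best_poses.append(poses[0])
        except Exception:  # noqa: BLE001 - a screen must survive bad records
            log.exception("screening failed for %r", ens.molecule.name)
            scores.append(-np.inf)
            best_poses.append(None)
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    table = pd.DataFrame({"name": names, "score": scores, "rank": ranks})
    auc = None
    if labels is not None:
        table["label"] = list(labels)
        auc = roc_auc(np.asarray(scores, dtype=float), np.asarray(labels))
    return ScreenResult(table=table, poses=best_poses, auc=auc)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area: the Mann-Whitney probability that a random active outscores
    a random decoy, ties counted 0.5."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least one active and one decoy")
    finite = np.where(np.isfinite(scores), scores,
                      np.min(scores[np.isfinite(scores)], initial=0.0) - 1.0)
    return float(roc_auc_score(labels, finite))


def paired_auc_test(auc_a: Sequence[float],
                    auc_b: Sequence[float]) -> dict[str, float]:
    """Two-tailed paired t-test between per-target AUC vectors, with a
    Kolmogorov-Smirnov normality check of the paired differences.

    Returns t, p, n, ks_stat, ks_p; zero-variance differences flag the
    result as degenerate (p is NaN).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    out: dict[str, float] = {"n": float(a.size)}
    if sd == 0:
        out.update(t=np.nan, p=np.nan, degenerate=1.0,
                   ks_stat=np.nan, ks_p=np.nan)
        return out
    t, pval = stats.ttest_rel(a, b)
    ks_stat, ks_p = stats.kstest((diff - diff.mean()) / sd, "norm")
    out.update(t=float(t), p=float(pval), degenerate=0.0,
               ks_stat=float(ks_stat), ks_p=float(ks_p))
    return out


# ---------------------------------------------------------------------------
# Imprint indexing
# ---------------------------------------------------------------------------

def _shape_descriptor(mol: Molecule) -> np.ndarray:
    """Cheap rotation-invariant descriptor used only to pick a diverse basis
    panel: distance moments from centroid plus charge statistics."""
    c = mol.coords - mol.coords.mean(axis=0)
    d = np.linalg.norm(c, axis=1)
    q = mol.charges if mol.charges is not None else np.zeros(mol.n_atoms)
    return np.array([mol.n_atoms, d.mean(), d.std(), d.max(),
                     float(np.abs(q).sum()), float(q.min()), float(q.max()),
                     len(mol.donors), len(mol.acceptors)])


def select_basis(library: Sequence[ConformerEnsemble],
                 k: int = IMPRINT_DIMENSION) -> list[int]:
    """Deterministic max-min diversity pick of ``k`` basis molecules (indices
    into the library), seeded with the first entry."""
    if len(library) < k:
        raise ValueError(f"library smaller than basis size {k}")
    desc = np.array([_shape_descriptor(e.molecule_at(0)) for e in library])
    scale = desc.std(axis=0)
    scale[scale == 0] = 1.0
    desc = desc / scale
    chosen = [0]
    dmin = np.linalg.norm(desc - desc[0], axis=1)
    while len(chosen) < k:
        i = int(np.argmax(dmin))
        chosen.append(i)
        dmin = np.minimum(dmin, np.linalg.norm(desc - desc[i], axis=1))
    return sorted(chosen)


def imprint(ens: ConformerEnsemble, basis_obs: Sequence[ObserverSet],
            mode: str | SearchMode = "pfast",
            params: Optional[SimParams] = None) -> np.ndarray:
    """The imprint vector: maximal similarity of the molecule against each
    basis molecule's observer set."""
    values = []
    for obs in basis_obs:
        poses = align(ens, obs, mode=mode, top_n=1, params=params)
        values.append(poses[0].score if poses else -np.inf)
    return np.asarray(values)


def imprint_rank(library: Sequence[ConformerEnsemble],
                 query: ConformerEnsemble,
                 basis_obs: Sequence[ObserverSet],
                 mode: str | SearchMode = "pfast",
                 params: Optional[SimParams] = None,
                 strict_dimension: bool = True) -> pd.DataFrame:
    """Rank a library by Euclidean distance between library imprints and the
    query imprint.  The basis panel must have exactly 20 members unless
    ``strict_dimension`` is disabled."""
    if strict_dimension and len(basis_obs) != IMPRINT_DIMENSION:
        raise ValueError(f"basis must contain exactly {IMPRINT_DIMENSION} "
                         f"molecules, got {len(basis_obs)}")
    q = imprint(query, basis_obs, mode, params)
    rows = []
    for ens in library:
        v = imprint(ens, basis_obs, mode, params)
        rows.append((ens.molecule.name, float(np.linalg.norm(v - q))))
    df = pd.DataFrame(rows, columns=["name", "distance"])
    df["rank"] = df["distance"].rank(method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)
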