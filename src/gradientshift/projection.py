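"""Projection of activation maps into gradient space and shift metrics.

Each subject x condition contrast vector is compared with each canonical
gradient map by Pearson correlation over the shared analysis mask; the
similarity r is Fisher z-transformed (arctanh, with |r| clipped just below 1
so degenerate perfectly-correlated inputs cannot overflow).  Shift scores are
Regulate-minus-Look differences of z per gradient (dG1..dGK), and Euclidean
reconfiguration distances are straight-line distances between the two
conditions' z-coordinate points, over all K gradients (ed5 for K = 5) or a
subset (ed3 for G1-G3).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import ActivationMap, Condition
from .simulate import GradientBasis

__all__ = [
    "DEFAULT_R_CLIP",
    "project_map",
    "projection_table",
    "shift_scores",
    "euclidean_shift",
    "shift_table",
    "region_shift_table",
]

DEFAULT_R_CLIP = 1.0 - 1e-12


def _pearson_many(x: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Pearson r of x against each column of G (columns = gradients)."""
    xc = x - x.mean()
    Gc = G - G.mean(axis=0, keepdims=True)
    xn = np.sqrt(np.sum(xc * xc))
    Gn = np.sqrt(np.sum(Gc * Gc, axis=0))
    if xn == 0:
        raise ValueError("zero-variance activation map: correlation undefined")
    if np.any(Gn == 0):
        raise ValueError("zero-variance gradient map: correlation undefined")
    return (Gc.T @ xc) / (Gn * xn)


def project_map(
    amap: ActivationMap | np.ndarray,
    basis: GradientBasis,
    r_clip: float = DEFAULT_R_CLIP,
) -> pd.DataFrame:
    """Per-gradient similarity (r) and Fisher z of one activation map.

    Returns a DataFrame with one row per gradient: columns
    ``gradient_id`` (1-based), ``r``, ``z``.
    """
    vec = amap.vector if isinstance(amap, ActivationMap) else np.asarray(amap, float)
    if vec.size != basis.maps.shape[0]:
        raise ValueError("map and basis do not share the analysis mask")
    r = _pearson_many(vec, basis.maps)
    z = np.arctanh(np.clip(r, -r_clip, r_clip))
    return pd.DataFrame(
        {"gradient_id": np.arange(1, basis.K + 1), "r": r, "z": z}
    )


def projection_table(
    maps: Sequence[ActivationMap], basis: GradientBasis,
    r_clip: float = DEFAULT_R_CLIP,
) -> pd.DataFrame:
    """Long-format projection table over many maps.

    Columns: subject_id, condition, gradient_id, r, z.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no activation maps supplied")
    # vectorized across maps: one centered cross-product instead of a
    # per-map loop (identical arithmetic to project_map)
    X = np.stack([m.vector for m in maps])            # (n_maps, V)
    Xc = X - X.mean(axis=1, keepdims=True)
    Gc = basis.maps - basis.maps.mean(axis=0, keepdims=True)
    xn = np.sqrt(np.sum(Xc * Xc, axis=1))
    gn = np.sqrt(np.sum(Gc * Gc, axis=0))
    if np.any(xn == 0):
        raise ValueError("zero-variance activation map: correlation undefined")
    if np.any(gn == 0):
        raise ValueError("zero-variance gradient map: correlation undefined")
    r = (Xc @ Gc) / np.outer(xn, gn)                  # (n_maps, K)
    z = np.arctanh(np.clip(r, -r_clip, r_clip))
    K = basis.K
    return pd.DataFrame({
        "subject_id": np.repeat([m.subject_id for m in maps], K),
        "condition": np.repeat([m.condition.value for m in maps], K),
        "gradient_id": np.tile(np.arange(1, K + 1), len(maps)),
        "r": r.ravel(),
        "z": z.ravel(),
    })


def shift_scores(proj_look: pd.DataFrame, proj_regulate: pd.DataFrame) -> np.ndarray:
    """Elementwise z difference, Regulate minus Look, aligned on gradient_id."""
    gl = proj_look.sort_values("gradient_id")
    gr = proj_regulate.sort_values("gradient_id")
    if not np.array_equal(gl["gradient_id"].to_numpy(), gr["gradient_id"].to_numpy()):
        raise ValueError("projections cover different gradient sets")
    return gr["z"].to_numpy() - gl["z"].to_numpy()


def euclidean_shift(
    proj_look: pd.DataFrame, proj_regulate: pd.DataFrame,
    dims: Sequence[int] | None = None,
) -> float:
    """Euclidean distance between the two conditions' z-coordinates.

    ``dims`` selects gradient ids (1-based); default is all available.
    """
    gl = proj_look.set_index("gradient_id")["z"]
    gr = proj_regulate.set_index("gradient_id")["z"]
    if dims is None:
        dims = list(gl.index)
    dims = list(dims)
    if not dims:
        raise ValueError("empty gradient subset for Euclidean shift")
    missing = [d for d in dims if d not in gl.index or d not in gr.index]
    if missing:
        raise ValueError(f"gradients not available: {missing}")
    diff = gr.loc[dims].to_numpy() - gl.loc[dims].to_numpy()
    return float(np.sqrt(np.sum(diff * diff)))


def shift_table(projections: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject shift table from a long projection table.

    Columns: subject_id, dG1..dGK, ed5 (distance over all K gradients),
    ed3 (G1-G3, present when K >= 3).
    """
    piv = projections.pivot(index="subject_id",
                            columns=["condition", "gradient_id"], values="z")
    order = pd.unique(projections["subject_id"])
    piv = piv.reindex(order)
    for cond in (Condition.LOOK.value, Condition.REGULATE.value):
        if cond not in piv.columns.get_level_values(0):
            raise ValueError(f"missing {cond} projections")
    look = piv[Condition.LOOK.value].sort_index(axis=1)
    reg = piv[Condition.REGULATE.value].sort_index(axis=1)
    incomplete = look.isna().any(axis=1) | reg.isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"subject {piv.index[incomplete][0]}: missing a condition projection")
    dg = reg.to_numpy() - look.to_numpy()
    out = pd.DataFrame({"subject_id": piv.index.to_numpy()})
    for k in range(dg.shape[1]):
        out[f"dG{k + 1}"] = dg[:, k]
    out["ed5"] = np.linalg.norm(dg, axis=1)
    if dg.shape[1] >= 3:
        out["ed3"] = np.linalg.norm(dg[:, :3], axis=1)
    return out


def region_shift_table(
    maps: Sequence[ActivationMap],
    basis: GradientBasis,
    atlas,
    family: str | None = None,
    gradient_id: int = 1,
    r_clip: float = DEFAULT_R_CLIP,
) -> pd.DataFrame:
    """Per-region gradient shifts: the projection/shift logic restricted to
    each atlas region's voxels (region ∩ mask).

    For every subject and region, the similarity of each condition map with
    gradient ``gradient_id`` is computed over that region's surviving voxels,
    Fisher z-transformed, and differenced Regulate - Look.  Regions with
    fewer than 3 surviving voxels or degenerate variance yield NaN (absent,
    not zero).  Returns rows (subject_id, family, region_id, dG).
    """
    mask = basis.mask
    if atlas.grid_shape != mask.grid_shape:
        raise ValueError("atlas and analysis mask grids differ")
    labels_flat = atlas.labels.ravel(order="C")[mask.indices]
    g = basis.maps[:, gradient_id - 1]
    fam = family if family is not None else atlas.family

    by_subject: dict[str, dict[str, np.ndarray]] = {}
    for amap in maps:
        by_subject.setdefault(amap.subject_id, {})[amap.condition.value] = amap.vector

    def _z(vec: np.ndarray, grad: np.ndarray) -> float:
        vc = vec - vec.mean()
        gc = grad - grad.mean()
        denom = np.sqrt((vc @ vc) * (gc @ gc))
        if denom == 0:
            return np.nan
        r = float(np.clip((vc @ gc) / denom, -r_clip, r_clip))
        return float(np.arctanh(r))

    rows = []
    for rid in atlas.region_ids:
        sel = labels_flat == rid
        n_vox = int(np.count_nonzero(sel))
        g_r = g[sel]
        for sid, conds in by_subject.items():
            if n_vox < 3 or set(conds) != {Condition.LOOK.value,
                                           Condition.REGULATE.value}:
                dg = np.nan
            else:
                z_l = _z(conds[Condition.LOOK.value][sel], g_r)
                z_r = _z(conds[Condition.REGULATE.value][sel], g_r)
                dg = z_r - z_l
            rows.append({"subject_id": sid, "family": fam,
                         "region_id": int(rid), "dG": dg})
    return pd.DataFrame(rows)
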