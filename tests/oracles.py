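"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (set counting, O(n^2) all-pairs
distances, voxel enumeration) so it cannot share a defect with the
library code it checks.
"""

import numpy as np


def set_counts(A, B):
    a = {tuple(i) for i in np.argwhere(np.asarray(A, dtype=bool))}
    b = {tuple(i) for i in np.argwhere(np.asarray(B, dtype=bool))}
    tp = len(a & b)
    fp = len(b - a)
    fn = len(a - b)
    tn = np.asarray(A).size - tp - fp - fn
    return tp, fp, fn, tn


def brute_boundary(mask):
    """Foreground voxels with an in-grid face-adjacent background voxel."""
    M = np.asarray(mask, dtype=bool)
    out = []
    for idx in np.argwhere(M):
        for ax in range(3):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if 0 <= nb[ax] < M.shape[ax] and not M[tuple(nb)]:
                    out.append(tuple(idx))
                    break
            else:
                continue
            break
    return np.array(sorted(out)).reshape(-1, 3)


def brute_directed_distances(src_pts, dst_pts, spacing):
    """All-pairs O(n*m) distance matrix, minimised per source point."""
    sp = np.asarray(spacing, dtype=float)
    diff = (src_pts[:, None, :] - dst_pts[None, :, :]) * sp
    return np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)


def brute_surface_distances(A, B, spacing=(1, 1, 1)):
    pa, pb = brute_boundary(A), brute_boundary(B)
    dab = brute_directed_distances(pa, pb, spacing)
    dba = brute_directed_distances(pb, pa, spacing)
    return dab, dba


def brute_metrics(A, B, spacing=(1, 1, 1), pa=None, pb=None):
    """All 12 report quantities from first principles; nan when undefined.

    ``pa``/``pb`` allow precomputed brute boundaries (boundaries depend on
    one mask only, so exhaustive enumerations can share them).
    """
    tp, fp, fn, tn = set_counts(A, B)
    na, nb = tp + fn, tp + fp

    def frac(n, d):
        return n / d if d else float("nan")

    out = dict(
        dice=1.0 if na + nb == 0 else 2 * tp / (na + nb),
        jaccard=1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn),
        precision=frac(tp, tp + fp),
        recall=frac(tp, tp + fn),
        fpr=frac(fp, fp + tn),
        fnr=frac(fn, tp + fn),
        vs=0.0 if 2 * tp + fp + fn == 0 else abs(fn - fp) / (2 * tp + fp + fn),
        volume_error_rate=frac(abs(nb - na) * 100.0, na),
    )
    if pa is None:
        pa = brute_boundary(A)
    if pb is None:
        pb = brute_boundary(B)
    if len(pa) and len(pb):
        dab = brute_directed_distances(pa, pb, spacing)
        dba = brute_directed_distances(pb, pa, spacing)
        d = np.concatenate([dab, dba])
        out.update(hd=max(dab.max(), dba.max()),
                   msd=float(np.mean(d ** 2)),
                   stdsd=float(np.sqrt(np.mean((d - d.mean()) ** 2))),
                   hd95=float(np.percentile(d, 95.0)))
    else:
        out.update(hd=float("nan"), msd=float("nan"), stdsd=float("nan"),
                   hd95=float("nan"))
    return out


def signed_mesh_volume(vertices, faces):
    """Sum of signed tetrahedra volumes over the faces of a closed mesh."""
    total = 0.0
    for f in faces:
        a, b, c = vertices[f[0]], vertices[f[1]], vertices[f[2]]
        total += np.dot(a, np.cross(b, c)) / 6.0
    return abs(total)


def cylinder_plane_count(z0, z1, spacing, extent):
    """Planes whose voxel-centre z lies inside [z0, z1]."""
    centers = (np.arange(extent) + 0.5) * spacing
    return int(((centers >= z0) & (centers <= z1)).sum())
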