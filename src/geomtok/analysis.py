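"""Reporting analyses: free-energy surfaces over learned CVs, fraction of
native contacts, CV surfaces over physical coordinates, and attention-map
summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binned_statistic_2d

from .errors import InputError

__all__ = ["pmf_2d", "ContactDefinition", "native_contact_pairs",
           "fraction_native_contacts", "window_frames", "cv_surface",
           "attention_report", "plot_attention"]

KB_KCAL_PER_MOL_K = 0.0019872041


def pmf_2d(cv_pairs: np.ndarray, bins: int = 50,
           temperature_units: str = "kT", temperature: float | None = None):
    """Potential of mean force F = −ln(histogram density), shifted so the
    minimum is 0; empty bins are masked.  With ``temperature_units=
    'kcal_per_mol'`` the surface is multiplied by k_B·T (temperature in
    kelvin required).

    Returns (F masked array [bins, bins], x_edges, y_edges).
    """
    cv = np.asarray(cv_pairs, dtype=np.float64)
    if cv.ndim != 2 or cv.shape[1] != 2 or cv.shape[0] < 1:
        raise InputError("cv_pairs must be [T, 2] with T >= 1")
    if bins < 2:
        raise InputError("bins must be >= 2")
    H, xe, ye = np.histogram2d(cv[:, 0], cv[:, 1], bins=bins, density=True)
    if np.count_nonzero(H) <= 1:
        import warnings
        warnings.warn("degenerate PMF grid: all samples in one bin")
    F = np.ma.masked_where(H <= 0, H)
    F = -np.ma.log(F)
    F = F - F.min()
    if temperature_units == "kcal_per_mol":
        if temperature is None:
            raise InputError("kcal/mol units require an explicit temperature")
        F = F * (KB_KCAL_PER_MOL_K * temperature)
    elif temperature_units != "kT":
        raise InputError(f"unknown units {temperature_units!r}")
    return F, xe, ye


@dataclass(frozen=True)
class ContactDefinition:
    """Native contacts of a reference structure: residue pairs three or
    more positions apart in sequence with at least one heavy-atom
    (non-hydrogen) distance below the threshold in the reference."""

    ref_coords: np.ndarray       # [N, 3] Å
    residue_ids: np.ndarray      # [N]
    atom_numbers: np.ndarray     # [N]
    threshold: float = 4.5       # Å
    min_separation: int = 3


def _residue_atom_lists(cd: ContactDefinition):
    heavy = np.asarray(cd.atom_numbers) != 1
    res = np.asarray(cd.residue_ids)
    return {r: np.nonzero((res == r) & heavy)[0] for r in np.unique(res)}


def native_contact_pairs(cd: ContactDefinition) -> list:
    """Residue pairs (i, j), j − i ≥ min_separation, in contact in the
    reference structure."""
    atoms = _residue_atom_lists(cd)
    residues = sorted(atoms)
    ref = np.asarray(cd.ref_coords, dtype=np.float64)
    pairs = []
    for a, ri in enumerate(residues):
        for rj in residues[a + 1:]:
            if abs(rj - ri) < cd.min_separation:
                continue
            ia, ja = atoms[ri], atoms[rj]
            if len(ia) == 0 or len(ja) == 0:
                continue
            dmin = np.sqrt(
                ((ref[ia][:, None, :] - ref[ja][None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin < cd.threshold:
                pairs.append((ri, rj))
    return pairs


def window_frames(window_time: float, frame_spacing: float) -> int:
    """Convert a smoothing window from time units to frames (e.g. 1 ns at
    0.2 ns/frame → 5 frames)."""
    return max(1, int(round(window_time / frame_spacing)))


def fraction_native_contacts(frames: np.ndarray, cd: ContactDefinition,
                             window: int = 1):
    """Per-frame fraction of native contacts Q and its centered moving
    average Q̄ over ``window`` frames.

    A native contact is counted in a frame when the same heavy-atom
    minimum-distance criterion (< threshold) holds there.
    """
    pairs = native_contact_pairs(cd)
    if not pairs:
        raise InputError("reference structure has no native contacts")
    frames = np.asarray(frames, dtype=np.float64)
    atoms = _residue_atom_lists(cd)
    T = frames.shape[0]
    hits = np.zeros((T, len(pairs)))
    for k, (ri, rj) in enumerate(pairs):
        ia, ja = atoms[ri], atoms[rj]
        d = np.sqrt(((frames[:, ia, None, :] - frames[:, None, ja, :]) ** 2
                     ).sum(-1)).reshape(T, -1).min(axis=1)
        hits[:, k] = d < cd.threshold
    Q = hits.mean(axis=1)
    if window <= 1:
        return Q, Q.copy()
    half = window // 2
    Qbar = np.array([
        Q[max(0, t - half): t + half + 1].mean() for t in range(T)
    ])
    return Q, Qbar


def cv_surface(cv: np.ndarray, coord_x: np.ndarray, coord_y: np.ndarray,
               bins: int = 30):
    """Binned mean of a CV over two physical coordinates; empty bins
    masked.  Returns (masked grid, x_edges, y_edges)."""
    cv, x, y = (np.asarray(a, dtype=np.float64).ravel()
                for a in (cv, coord_x, coord_y))
    if not len(cv) == len(x) == len(y):
        raise InputError("cv and coordinates must have equal lengths")
    mean, xe, ye, _ = binned_statistic_2d(x, y, cv, statistic="mean",
                                          bins=bins)
    return np.ma.masked_invalid(mean), xe, ye


def attention_report(maps, labels=None, token_names=None) -> dict:
    """Summarize per-frame attention maps.

    maps: list over layers of arrays [T, L, L] (head-averaged,
    row-stochastic).  Returns per-layer global averages, per-state
    averages weighted naturally by state frame counts (so they recompose
    the global average exactly), and row/column activity sums.
    """
    maps = [np.asarray(m, dtype=np.float64) for m in maps]
    T = maps[0].shape[0]
    if labels is not None and len(np.asarray(labels)) != T:
        raise InputError("labels must align with frames")
    report = {
        "global": [m.mean(axis=0) for m in maps],
        "token_names": token_names,
    }
    report["row_activity"] = [g.sum(axis=1) for g in report["global"]]
    report["col_activity"] = [g.sum(axis=0) for g in report["global"]]
    if labels is not None:
        labels = np.asarray(labels)
        states = np.unique(labels)
        report["per_state"] = {
            int(s): [m[labels == s].mean(axis=0) for m in maps]
            for s in states
        }
        report["state_weights"] = {
            int(s): float((labels == s).mean()) for s in states
        }
    return report


def plot_attention(report: dict, path, layer: int = 0) -> None:
    """Render a log-scaled attention heatmap with token labels; the
    global token is labelled '*'."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amap = report["global"][layer]
    L = amap.shape[0]
    names = report.get("token_names")
    if names is None or len(names) == L - 1:
        names = ["*"] + list(names or [str(i) for i in range(L - 1)])
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(np.log10(np.maximum(amap, 1e-12)), cmap="viridis")
    ax.set_xticks(range(L), names, rotation=90, fontsize=6)
    ax.set_yticks(range(L), names, fontsize=6)
    fig.colorbar(im, ax=ax, label="log10 attention")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
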