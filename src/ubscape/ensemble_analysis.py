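"""Per-frame order parameters and ensemble statistics for diUb landscapes.

Order parameters follow the conventions used throughout the analysis:
d_com is the distance between the unweighted bead centroids of the two
monomers; patch distances are centroid-to-centroid distances of the I44
(L8, I44, V70) and I36 (L8, I36, L71, L73) hydrophobic surface patches;
d_I36I44 is the minimum over the two cross pairings; d_M1G76 links the
distal N-terminus to the proximal C-terminus (the smFRET-style
coordinate).  Free-energy surfaces are -k_B T ln P over binned order
parameters, shifted so the global minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB
from .model_builder import BeadModel

__all__ = [
    "PatchDefinition", "I44_PATCH", "I36_PATCH", "OrderParams", "FES",
    "ContactProfile", "compute_order_params", "order_param_table",
    "kabsch_rmsd", "fes_1d", "fes_2d", "interfacial_contact_profile",
    "symmetry_score", "rmsf", "autocorrelation_time",
]


@dataclass(frozen=True)
class PatchDefinition:
    name: str
    residues: tuple


#: hydrophobic surface patches of ubiquitin
I44_PATCH = PatchDefinition("I44", (8, 44, 70))
I36_PATCH = PatchDefinition("I36", (8, 36, 71, 73))


@dataclass
class OrderParams:
    d_com: float
    d_i44i44: float
    d_i36i36: float
    d_i36i44: float
    d_m1g76: float
    rmsd_to: dict = field(default_factory=dict)
    e_elec: float = 0.0
    e_hp: float = 0.0
    e_total: float = 0.0


@dataclass
class FES:
    axes: tuple                    # axis names
    edges: tuple                   # bin edge arrays
    free_energy: np.ndarray        # k_B T units, masked NaN where empty
    counts: np.ndarray


@dataclass
class ContactProfile:
    distal: np.ndarray             # mean interfacial contacts per residue
    proximal: np.ndarray
    residues: np.ndarray
    n_frames: int
    d_com_max: float
    matrix: np.ndarray | None = None   # residue-residue contact frequency


# ---------------------------------------------------------------------------

def _monomer_masks(model: BeadModel):
    mono = model.monomer_labels()
    return mono == 0, mono == 1


def wrap_dimer(xyz: np.ndarray, model: BeadModel,
               box: float | None) -> np.ndarray:
    """Remap the proximal monomer to the periodic image nearest the
    distal one, so inter-monomer geometry is meaningful.

    Individual monomers are held together by bonds and are never split;
    only the whole-monomer image needs fixing.
    """
    if not box:
        return np.asarray(xyz, dtype=float)
    xyz = np.array(xyz, dtype=float)
    m0, m1 = _monomer_masks(model)
    d = xyz[m1].mean(axis=0) - xyz[m0].mean(axis=0)
    xyz[m1] -= box * np.rint(d / box)
    return xyz


def _patch_center(xyz, model: BeadModel, mask, patch: PatchDefinition):
    resid = model.res_indices()
    sel = mask & np.isin(resid, patch.residues)
    return xyz[sel].mean(axis=0)


def compute_order_params(xyz: np.ndarray, model: BeadModel,
                         references: dict | None = None,
                         box: float | None = None) -> OrderParams:
    """All order parameters of one two-monomer frame.

    ``references`` maps name -> reference BeadModel for RMSD computation
    (backbone-bead selection).  ``box`` applies the minimum-image
    remapping of :func:`wrap_dimer` first.
    """
    if model.n_monomers != 2:
        raise ValueError("order parameters require a two-monomer model")
    xyz = wrap_dimer(xyz, model, box)
    m0, m1 = _monomer_masks(model)
    d_com = float(np.linalg.norm(xyz[m0].mean(axis=0) - xyz[m1].mean(axis=0)))

    c44_0 = _patch_center(xyz, model, m0, I44_PATCH)
    c44_1 = _patch_center(xyz, model, m1, I44_PATCH)
    c36_0 = _patch_center(xyz, model, m0, I36_PATCH)
    c36_1 = _patch_center(xyz, model, m1, I36_PATCH)
    d4444 = float(np.linalg.norm(c44_0 - c44_1))
    d3636 = float(np.linalg.norm(c36_0 - c36_1))
    d3644 = float(min(np.linalg.norm(c36_0 - c44_1), np.linalg.norm(c44_0 - c36_1)))

    resid = model.res_indices()
    kinds = model.kinds()
    i_m1 = np.where(m0 & (resid == resid[m0].min()) & (kinds == 0))[0][0]
    i_g76 = np.where(m1 & (resid == resid[m1].max()) & (kinds == 0))[0][0]
    d_m1g76 = float(np.linalg.norm(xyz[i_m1] - xyz[i_g76]))

    rmsds = {}
    if references:
        for name, ref in references.items():
            rmsds[name] = kabsch_rmsd(xyz, model, ref)  # already wrapped
    return OrderParams(d_com=d_com, d_i44i44=d4444, d_i36i36=d3636,
                       d_i36i44=d3644, d_m1g76=d_m1g76, rmsd_to=rmsds)


def order_param_table(trajectory, model: BeadModel,
                      references: dict | None = None) -> dict:
    """Vectorised per-frame order parameters for a whole trajectory.

    Returns a dict of 1-D arrays keyed like the OrderParams fields, with
    interfacial E_elec / E_HP taken from the recorded energy terms when
    the trajectory carries them.
    """
    names = ["d_com", "d_i44i44", "d_i36i36", "d_i36i44", "d_m1g76"]
    cols = {n: [] for n in names}
    rmsd_cols: dict = {}
    box = getattr(trajectory, "box", None)
    for k in range(trajectory.frames.shape[0]):
        op = compute_order_params(trajectory.frames[k], model, references,
                                  box=box)
        for n in names:
            cols[n].append(getattr(op, n))
        for rn, rv in op.rmsd_to.items():
            rmsd_cols.setdefault(f"rmsd_{rn}", []).append(rv)
    out = {n: np.array(v) for n, v in cols.items()}
    for rn, rv in rmsd_cols.items():
        out[rn] = np.array(rv)
    if trajectory.energies is not None and trajectory.energies.size:
        out["e_elec"] = trajectory.energies[:, 6]
        out["e_hp"] = trajectory.energies[:, 7]
        out["e_total"] = trajectory.energies.sum(axis=1)
    return out


# ---------------------------------------------------------------------------

def kabsch_rmsd(xyz: np.ndarray, model: BeadModel, reference: BeadModel,
                selection: str = "backbone") -> float:
    """Least-squares optimal superposition RMSD (nm) against a reference.

    Default selection: backbone beads of both units (reference structures
    differ in sidechain completeness).
    """
    sel_m = _selection_mask(model, selection)
    sel_r = _selection_mask(reference, selection)
    a = np.asarray(xyz, dtype=float)[sel_m]
    b = reference.coords()[sel_r]
    if a.shape != b.shape:
        raise ValueError(
            f"selection size mismatch: frame {a.shape[0]} vs reference {b.shape[0]}"
        )
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    a_rot = rot.apply(a)
    return float(np.sqrt(np.mean(np.sum((a_rot - b) ** 2, axis=1))))


def _selection_mask(model: BeadModel, selection: str) -> np.ndarray:
    kinds = model.kinds()
    if selection == "backbone":
        return kinds == 0
    if selection == "all":
        return np.ones(len(model), bool)
    raise ValueError(f"unknown selection {selection!r}")


# ---------------------------------------------------------------------------

def fes_1d(x, bins=50, kbt: float = 1.0, range=None) -> FES:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    counts, edges = np.histogram(x, bins=bins, range=range)
    f = _counts_to_free_energy(counts, kbt)
    return FES(axes=("x",), edges=(edges,), free_energy=f, counts=counts)


def fes_2d(x, y, bins=50, kbt: float = 1.0, range=None) -> FES:
    """Two-dimensional free-energy surface F = -k_B T ln P, minimum 0.

    Empty bins are NaN (flagged, never imputed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    counts, ex, ey = np.histogram2d(x, y, bins=bins, range=range)
    f = _counts_to_free_energy(counts, kbt)
    return FES(axes=("x", "y"), edges=(ex, ey), free_energy=f, counts=counts)


def _counts_to_free_energy(counts: np.ndarray, kbt: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(counts.astype(float))
    f[counts == 0] = np.nan
    return f - np.nanmin(f)


# ---------------------------------------------------------------------------

def interfacial_contact_profile(frames, model: BeadModel,
                                cutoff: float = 0.8,
                                d_com_max: float = 3.2,
                                box: float | None = None) -> ContactProfile:
    """Per-residue mean interfacial contact counts over bound frames.

    A contact is any inter-monomer bead pair within ``cutoff`` nm; only
    frames with d_com <= ``d_com_max`` qualify.  Also returns the full
    residue-residue contact-frequency matrix.
    """
    import warnings

    m0, m1 = _monomer_masks(model)
    resid = model.res_indices()
    res0 = np.unique(resid[m0])
    res1 = np.unique(resid[m1])
    all_res = np.unique(np.concatenate([res0, res1]))
    nres = all_res.size
    rmap = {r: k for k, r in enumerate(all_res)}
    prof0 = np.zeros(nres)
    prof1 = np.zeros(nres)
    matrix = np.zeros((nres, nres))
    idx0 = np.where(m0)[0]
    idx1 = np.where(m1)[0]
    used = 0
    for xyz in frames:
        xyz = wrap_dimer(xyz, model, box)
        if np.linalg.norm(xyz[m0].mean(axis=0) - xyz[m1].mean(axis=0)) > d_com_max:
            continue
        used += 1
        d2 = np.sum((xyz[idx0, None, :] - xyz[None, idx1, :]) ** 2, axis=-1)
        ii, jj = np.nonzero(d2 <= cutoff * cutoff)
        for a, b in zip(idx0[ii], idx1[jj]):
            ra, rb = rmap[resid[a]], rmap[resid[b]]
            prof0[ra] += 1
            prof1[rb] += 1
            matrix[ra, rb] += 1
    if used == 0:
        warnings.warn("no frames pass the d_com filter; empty profile",
                      stacklevel=2)
        return ContactProfile(prof0, prof1, all_res, 0, d_com_max, matrix)
    return ContactProfile(prof0 / used, prof1 / used, all_res, used,
                          d_com_max, matrix / used)


def hot_spots(profile: ContactProfile, threshold: float = 1.0):
    """Residues with more than ``threshold`` mean interfacial contacts."""
    return (profile.residues[profile.distal > threshold],
            profile.residues[profile.proximal > threshold])


def symmetry_score(distal: np.ndarray, proximal: np.ndarray) -> float:
    """Pearson correlation between the distal and proximal per-residue
    interfacial contact profiles; NaN if either has zero variance."""
    a = np.asarray(distal, dtype=float)
    b = np.asarray(proximal, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------

def rmsf(frames, model: BeadModel, selection: str = "backbone") -> np.ndarray:
    """Root-mean-square fluctuation (nm) per selected bead, after
    per-frame optimal superposition onto the mean structure."""
    sel = _selection_mask(model, selection)
    xs = np.array([np.asarray(f, dtype=float)[sel] for f in frames])
    if xs.shape[0] < 2:
        raise ValueError("need at least two frames")
    ref = xs[0] - xs[0].mean(axis=0)
    for _ in range(2):  # align to mean, iterate once for stability
        aligned = np.empty_like(xs)
        for k in range(xs.shape[0]):
            a = xs[k] - xs[k].mean(axis=0)
            rot, _r = Rotation.align_vectors(ref, a)
            aligned[k] = rot.apply(a)
        ref = aligned.mean(axis=0)
    dev = aligned - ref
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def autocorrelation_time(series: np.ndarray) -> tuple:
    """Integrated autocorrelation time (frames) and the convergence index
    n_frames / tau.  Flags the estimate unreliable when the series is
    shorter than ~10 tau."""
    import emcee.autocorr as ac

    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short")
    try:
        tau = float(ac.integrated_time(x, quiet=True)[0])
        reliable = x.size >= 10 * tau
    except ac.AutocorrError:
        tau = float(x.size)
        reliable = False
    return tau, x.size / tau, reliable
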