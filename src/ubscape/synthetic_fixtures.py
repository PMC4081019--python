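"""Download-free synthetic test inputs.

Three families of fixtures, all generated from a seed and byte-reproducible:

* a miniature two-domain dimer (12-residue beta-hairpin domains) whose
  native conformation is the energy minimum of its own generated topology
  — exercises every model-building and energetics code path;
* state-mixture trajectories with exact ground-truth labels, for testing
  classification and population statistics;
* a two-bead harmonic system with closed-form moments, for integrator
  acceptance tests.

The module also provides a SYNTHETIC ubiquitin monomer: the real
76-residue sequence placed on an idealized secondary-structure fold
(five-stranded sheet in the native strand order beta2-beta1-beta5-beta3-
beta4 with the alpha1 helix packed on top).  It is a stand-in constructed
because no experimental ubiquitin coordinates can be redistributed here;
it emulates the native topology (e.g. the beta1/beta5 strand adjacency
that puts M1 next to K63) but not crystallographic geometry, and fixture
results must not be read as reproductions of experimental structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, UBIQUITIN_SEQUENCE, ONE_TO_THREE
from .dynamics import Trajectory
from .model_builder import (
    BeadModel,
    CGTopology,
    ResidueRecord,
    TopologyParams,
    assign_charges,
    build_hydrophobic_matrix,
    build_topology,
    coarse_grain,
    detect_native_contacts,
)

__all__ = [
    "MiniDimerSpec", "MixtureSpec", "make_mini_dimer",
    "make_state_mixture_trajectory", "make_harmonic_fixture",
    "ub_monomer_residues", "ub_dimer_system",
]


# ---------------------------------------------------------------------------
# miniature two-domain dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiniDimerSpec:
    n_residues: int = 12
    sequence: str = "LKELFGDAIKEF"    # hydrophobic + charged + neutral + Gly
    patch_a: tuple = (4, 8)           # mock surface patches (residue ids)
    patch_b: tuple = (2, 10)
    seed: int = 0
    domain_gap: float = 0.8           # facing-surface gap, nm


_STRAND_GAP = 0.44   # inter-strand C-alpha spacing, nm (beta-sheet like)


def _hairpin_calpha(n: int) -> np.ndarray:
    """Idealized beta-hairpin C-alpha trace: two antiparallel strands at
    beta-sheet spacing, 0.38 nm rise, two loop residues on top."""
    half = (n - 2) // 2
    pos = []
    for i in range(half):                       # strand A, going up
        pos.append((0.0, 0.0, 0.38 * i))
    top = 0.38 * (half - 1)
    pos.append((0.05, 0.30, top + 0.38))        # loop
    pos.append((0.39, 0.30, top + 0.38))
    for i in range(half):                       # strand B, coming down
        pos.append((_STRAND_GAP, 0.0, top - 0.38 * i))
    return np.array(pos[:n]) + _pleat(n)


def _mini_domain_residues(spec: MiniDimerSpec, rng: np.random.Generator,
                          chain_id: str, mirror: bool, x_shift: float) -> list:
    ca = _hairpin_calpha(spec.n_residues)
    ca = ca + rng.normal(0.0, 0.002, ca.shape)  # seed-deterministic jitter
    if mirror:  # jitter first: both domains are exact isometric copies
        ca = ca * np.array([-1.0, 1.0, 1.0])
    ca = ca + np.array([x_shift, 0.0, 0.0])
    residues = []
    half = (spec.n_residues - 2) // 2
    for i, one in enumerate(spec.sequence):
        name3 = ONE_TO_THREE[one]
        p = ca[i]
        tangent = (ca[min(i + 1, spec.n_residues - 1)] - ca[max(i - 1, 0)])
        tangent = tangent / np.linalg.norm(tangent)
        # pleated sidechains (+/- y), anti-aligned across the two strands
        if i < half:                    # strand A
            sign = 1.0 if i % 2 == 0 else -1.0
        elif i in (half, half + 1):     # loop residues point up
            sign = 0.0
        else:                           # strand B: opposite phase at equal z
            zi = round(ca[i][2] / 0.38)
            sign = -1.0 if zi % 2 == 0 else 1.0
        if sign == 0.0:
            sc_dir = np.array([0.0, 0.0, 1.0])
        else:
            sc_dir = np.array([0.0, sign, 0.0])
        atoms = [
            ("N", "N", (p - 0.12 * tangent) * 10.0, 1.0, ""),
            ("CA", "C", p * 10.0, 1.0, ""),
            ("C", "C", (p + 0.12 * tangent) * 10.0, 1.0, ""),
        ]
        if one != "G":
            atoms.append(("CB", "C", (p + 0.19 * sc_dir) * 10.0, 1.0, ""))
            if one not in "ASTCV":
                atoms.append(("CG", "C", (p + 0.35 * sc_dir) * 10.0, 1.0, ""))
        residues.append(ResidueRecord(chain_id, i + 1, name3,
                                      [(n, e, np.asarray(c), o, a)
                                       for n, e, c, o, a in atoms]))
    return residues


@dataclass
class MiniDimer:
    spec: MiniDimerSpec
    residues_distal: list
    residues_proximal: list
    model: BeadModel               # merged dimer, charges assigned
    topology: CGTopology
    contacts: list                 # monomer-local native contacts


def make_mini_dimer(spec: MiniDimerSpec = MiniDimerSpec(),
                    linkage: str = "free",
                    params: TopologyParams | None = None) -> MiniDimer:
    """Two identical folded mini-domains facing each other.

    The facing surfaces carry hydrophobic and charged sidechains so both
    the Debye-Hueckel and hydrophobic binding terms are exercised.
    """
    # both domains share one jitter stream: identical in sequence and fold
    rng_a = np.random.Generator(np.random.PCG64(spec.seed))
    rng_b = np.random.Generator(np.random.PCG64(spec.seed))
    res_a = _mini_domain_residues(spec, rng_a, "A", mirror=False, x_shift=0.0)
    # second domain mirrored so its strand-B face looks back at the first
    shift = 2 * _STRAND_GAP + spec.domain_gap
    res_b = _mini_domain_residues(spec, rng_b, "B", mirror=True, x_shift=shift)
    contacts = detect_native_contacts(res_a)
    m_a = coarse_grain(res_a, "distal")
    m_b = coarse_grain(res_b, "proximal")
    model, topo = build_topology([m_a, m_b], linkage=linkage,
                                 contacts=contacts, params=params)
    assign_charges(model)
    model.source_id = f"mini-dimer(seed={spec.seed})"
    return MiniDimer(spec, res_a, res_b, model, topo, contacts)


# ---------------------------------------------------------------------------
# state-mixture trajectories with ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    fractions: dict = field(default_factory=lambda: {
        "open": 0.15, "closed": 0.15, "other": 0.70})
    n_frames: int = 1000
    seed: int = 0
    jitter: float = 0.005          # per-bead positional noise, nm


def _exact_counts(fractions: dict, n: int) -> dict:
    """Largest-remainder allocation: counts sum exactly to n."""
    items = list(fractions.items())
    raw = [f * n for _, f in items]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for k in order[:rem]:
        base[k] += 1
    return {name: c for (name, _), c in zip(items, base)}


def make_state_mixture_trajectory(model: BeadModel, spec: MixtureSpec,
                                  cutoffs=None):
    """Geometric frames drawn from per-state templates, with exact
    multinomial counts and ground-truth labels.

    Templates place the I44/I36 patch centroids (not full interfaces) at
    distances that provably satisfy the classification rules; every frame
    is verified against its intended label at build time.
    """
    from .ensemble_analysis import I36_PATCH, I44_PATCH, compute_order_params
    from .states_thermo import StateCutoffs, classify_frame

    cutoffs = cutoffs or StateCutoffs()
    if not np.isclose(sum(spec.fractions.values()), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    counts = _exact_counts(spec.fractions, spec.n_frames)

    labels = []
    for s, c in counts.items():
        labels.extend([s] * c)
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)

    base = model.coords().copy()
    mono = model.monomer_labels()
    m0, m1 = mono == 0, mono == 1
    base[m0] -= base[m0].mean(axis=0)
    base[m1] -= base[m1].mean(axis=0)
    resid = model.res_indices()

    def place(xyz, mask, patch_res, target, moved):
        """Translate a patch's beads so its centroid hits ``target``;
        beads already moved by an earlier patch stay put (the remaining
        beads over-translate to compensate)."""
        sel = np.where(mask & np.isin(resid, patch_res))[0]
        free = np.array([i for i in sel if i not in moved])
        cur = xyz[sel].mean(axis=0)
        delta = (target - cur) * (len(sel) / max(len(free), 1))
        xyz[free] += delta
        moved.update(sel.tolist())

    frames = np.empty((spec.n_frames, base.shape[0], 3))
    c_open, c44, c36, c3644 = (cutoffs.open_dcom, cutoffs.closed_i44i44,
                               cutoffs.i36i36, cutoffs.i36i44)
    for k, lab in enumerate(labels):
        xyz = base.copy()
        if lab == "open":
            d = c_open + 0.8 + rng.uniform(0.0, 1.0)
            xyz[m1] += np.array([d, 0.0, 0.0])
        else:
            d = 2.0
            xyz[m1] += np.array([d, 0.0, 0.0])
            moved: set = set()
            far_y = 2.0
            if lab == "closed":
                t = c44 * rng.uniform(0.3, 0.9)
                place(xyz, m0, I44_PATCH.residues, np.array([(d - t) / 2, 0, 0]), moved)
                place(xyz, m1, I44_PATCH.residues, np.array([(d + t) / 2, 0, 0]), moved)
            elif lab == "I36-I36":
                t = c36 * rng.uniform(0.3, 0.9)
                place(xyz, m0, I44_PATCH.residues, np.array([d / 2 - 1.5, far_y, 0]), moved)
                place(xyz, m1, I44_PATCH.residues, np.array([d / 2 + 1.5, far_y, 0]), moved)
                place(xyz, m0, I36_PATCH.residues, np.array([(d - t) / 2, 0, 0]), moved)
                place(xyz, m1, I36_PATCH.residues, np.array([(d + t) / 2, 0, 0]), moved)
            elif lab == "I36-I44":
                t = c3644 * rng.uniform(0.3, 0.9)
                place(xyz, m0, I44_PATCH.residues, np.array([d / 2 - 1.5, far_y, 0]), moved)
                place(xyz, m1, I36_PATCH.residues, np.array([d / 2 + 1.5, far_y, 0]), moved)
                place(xyz, m0, I36_PATCH.residues, np.array([(d - t) / 2, 0, 0]), moved)
                place(xyz, m1, I44_PATCH.residues, np.array([(d + t) / 2, 0, 0]), moved)
            else:  # other compact
                place(xyz, m0, I44_PATCH.residues, np.array([d / 2 - 1.5, far_y, 0]), moved)
                place(xyz, m1, I44_PATCH.residues, np.array([d / 2 + 1.5, far_y, 0]), moved)
                place(xyz, m0, I36_PATCH.residues, np.array([d / 2 - 1.5, -far_y, 0]), moved)
                place(xyz, m1, I36_PATCH.residues, np.array([d / 2 + 1.5, -far_y, 0]), moved)
        xyz += rng.normal(0.0, spec.jitter, xyz.shape)
        op = compute_order_params(xyz, model)
        got = classify_frame(op, cutoffs)
        if got != lab:
            raise RuntimeError(
                f"state template for {lab!r} classified as {got!r}; "
                "template inconsistent with cutoffs"
            )
        frames[k] = xyz

    traj = Trajectory(frames=frames, times=np.arange(spec.n_frames, dtype=float),
                      energies=np.zeros((spec.n_frames, 8)),
                      kinetic=np.zeros(spec.n_frames), box=50.0, seed=spec.seed)
    return traj, labels


# ---------------------------------------------------------------------------
# harmonic two-bead fixture
# ---------------------------------------------------------------------------

def make_harmonic_fixture(k: float = 1000.0, r0: float = 0.5,
                          temperature: float = 50.0):
    """Two beads joined by V = k (r - r0)^2, plus the analytic bond-length
    variance <(r-r0)^2> = k_B T / (2 k) for integrator acceptance tests."""
    if k <= 0:
        raise ValueError("spring constant must be positive")
    from .model_builder import Bead

    beads = [
        Bead("distal", 1, "backbone", np.array([0.0, 0.0, 0.0]), res_type="A"),
        Bead("distal", 2, "backbone", np.array([r0, 0.0, 0.0]), res_type="A"),
    ]
    model = BeadModel(beads=beads, n_monomers=1, source_id="harmonic-fixture")
    topo = CGTopology(
        n_beads=2,
        bonds=np.array([[0, 1]]), bond_r0=np.array([r0]), bond_k=np.array([k]),
        angles=np.zeros((0, 3), int), angle_t0=np.zeros(0), angle_k=np.zeros(0),
        dihedrals=np.zeros((0, 4), int), dih_p0=np.zeros(0),
        dih_k1=np.zeros(0), dih_k3=np.zeros(0),
        contacts=np.zeros((0, 2), int), contact_rn=np.zeros(0),
        contact_eps=np.zeros(0),
        exclusions=np.array([[0, 1]]),
    )
    analytic = {"bond_variance": KB * temperature / (2.0 * k),
                "temperature": temperature}
    return model, topo, analytic


# ---------------------------------------------------------------------------
# synthetic ubiquitin stand-in
# ---------------------------------------------------------------------------

# secondary-structure layout: (first_res, last_res, kind, params)
# sheet strands sit in the xz plane (x = strand offset, z = rise);
# the native strand order across the sheet is beta2-beta1-beta5-beta3-beta4.
_SHEET_X = {"b1": 0.48, "b2": 0.0, "b3": 1.44, "b4": 1.92, "b5": 0.96}
_RISE = 0.35


def _ub_calpha_trace() -> np.ndarray:
    """Idealized C-alpha trace for the 76-residue ubiquitin fold.

    Anchored secondary-structure elements are placed first; connecting
    loops are then filled along arcs resampled to a uniform ~0.37 nm
    C-alpha spacing.
    """
    pos = np.zeros((76, 3))

    def strand(first, last, x, z_start, direction):
        for i in range(first, last + 1):
            pos[i - 1] = (x, 0.0, z_start + direction * _RISE * (i - first))

    strand(1, 7, _SHEET_X["b1"], 0.0, +1)          # beta1, up
    # hairpin loop 8-10 over the top of beta1/beta2
    pos[7] = (0.40, 0.30, 2.40)                    # L8
    pos[8] = (0.10, 0.40, 2.55)
    pos[9] = (0.00, 0.25, 2.30)
    strand(11, 17, _SHEET_X["b2"], 2.10, -1)       # beta2, down
    # alpha1 23-34: helix packed above the sheet, axis along -z
    for i in range(23, 35):
        t = i - 23
        ang = np.deg2rad(100.0) * t
        pos[i - 1] = (0.72 + 0.23 * np.cos(ang),
                      1.05 + 0.23 * np.sin(ang),
                      1.95 - 0.15 * t)
    strand(40, 45, _SHEET_X["b3"], 1.75, -1)       # beta3, down (antiparallel to beta5)
    # turn 46-47 and short beta4 48-49
    pos[45] = (1.70, 0.25, -0.30)
    pos[46] = (2.00, 0.30, -0.05)
    strand(48, 49, _SHEET_X["b4"], 0.10, +1)       # beta4, up
    # 3-10 helix 57-59
    pos[56] = (1.55, 0.75, 0.45)
    pos[57] = (1.35, 0.95, 0.20)
    pos[58] = (1.15, 0.75, 0.00)
    strand(66, 71, _SHEET_X["b5"], 0.0, +1)        # beta5, up (parallel to beta1)
    # flexible C-terminal tail 72-76 leaves the sheet top
    tail_dir = np.array([0.25, 0.35, 0.9])
    tail_dir /= np.linalg.norm(tail_dir)
    for i in range(72, 77):
        pos[i - 1] = pos[70] + tail_dir * 0.37 * (i - 71)
    # connecting loops (anchors already in place); the beta2->helix loop
    # detours in -x so it clears the helix body
    _fill_loop(pos, 17, 23, bulge=(-0.8, 0.4, 0.0), min_amp=0.5)
    _fill_loop(pos, 34, 40, bulge=(0.3, 0.45, 0.2))    # helix -> beta3
    _fill_loop(pos, 49, 57, bulge=(0.1, 0.85, 0.3))    # beta4 -> 3-10
    # 3-10 -> beta5: runs along the bottom sheet edge next to beta1
    _fill_loop(pos, 59, 66, bulge=(-0.5, 0.3, -0.35))
    return pos + _pleat(76)


def _pleat(n: int) -> np.ndarray:
    """Small alternating out-of-line offsets (beta-pleat-like).

    Ideal straight segments would put backbone angles exactly at the
    theta = pi singularity of the angle potential; real chains zigzag.
    """
    i = np.arange(n)
    dev = np.zeros((n, 3))
    dev[:, 0] = 0.03 * (-1.0) ** (i // 2)
    dev[:, 1] = 0.05 * (-1.0) ** i
    return dev


def _fill_loop(pos: np.ndarray, anchor_a: int, anchor_b: int, bulge,
               spacing: float = 0.37, min_amp: float = 0.0):
    """Fill residues between two anchors (1-based, exclusive) along a
    sine-bulged arc resampled to uniform C-alpha spacing.

    The bulge amplitude is solved so the arc length matches the number
    of residues times ``spacing`` (a straight line if the anchors are
    already far enough apart)."""
    a = pos[anchor_a - 1]
    b = pos[anchor_b - 1]
    n = anchor_b - anchor_a - 1
    target = (n + 1) * spacing
    u = np.asarray(bulge, dtype=float)
    u = u / np.linalg.norm(u)

    def curve(amp, m=400):
        f = np.linspace(0.0, 1.0, m)
        return a[None, :] + (b - a)[None, :] * f[:, None] \
            + u[None, :] * (amp * np.sin(np.pi * f))[:, None]

    def arclen(amp):
        c = curve(amp)
        return np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))

    if arclen(min_amp) >= target:
        amp = min_amp
    else:
        lo, hi = min_amp, max(min_amp, 0.1)
        while arclen(hi) < target:
            hi *= 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if arclen(mid) < target else (lo, mid)
        amp = 0.5 * (lo + hi)
    c = curve(amp)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(c, axis=0), axis=1))])
    want = np.linspace(0.0, s[-1], n + 2)[1:-1]
    for k, sk in enumerate(want):
        idx = np.searchsorted(s, sk)
        idx = min(max(idx, 1), len(s) - 1)
        f = (sk - s[idx - 1]) / max(s[idx] - s[idx - 1], 1e-12)
        pos[anchor_a + k] = c[idx - 1] + (c[idx] - c[idx - 1]) * f


#: sidechain direction rule per residue: -y face of the sheet carries the
#: hydrophobic patches, +y faces the helix
def _ub_sidechain_dir(i: int, trace: np.ndarray) -> np.ndarray:
    ca = trace[i - 1]
    in_strand = any(lo <= i <= hi for lo, hi in
                    ((1, 7), (11, 17), (40, 45), (48, 49), (66, 71)))
    if in_strand:
        sign = -1.0 if i % 2 == 0 else 1.0
        return np.array([0.0, sign, 0.0])
    if 23 <= i <= 34:  # helix: radial from axis
        d = ca - np.array([0.72, 1.05, ca[2]])
        n = np.linalg.norm(d)
        return d / n if n > 1e-9 else np.array([0.0, 1.0, 0.0])
    if i >= 72 or i == 8:  # tail and L8 join the patch face
        return np.array([0.0, -1.0, 0.0])
    # loops: point away from the fold centroid, orthogonal to the chain,
    # staggered laterally (alternating rotation about the tangent) so
    # consecutive sidechains do not collide
    centroid = trace.mean(axis=0)
    t = trace[min(i, 75)] - trace[max(i - 2, 0)]
    t = t / max(np.linalg.norm(t), 1e-9)
    out = ca - centroid
    out = out - (out @ t) * t
    out = out / max(np.linalg.norm(out), 1e-9)
    binorm = np.cross(out, t)
    a = 0.7 * (1.0 if i % 2 == 0 else -1.0)
    d = np.cos(a) * out + np.sin(a) * binorm
    return d / np.linalg.norm(d)


def ub_monomer_residues(seed: int = 0, jitter: float = 0.0) -> list:
    """SYNTHETIC ubiquitin monomer (all-atom-like ResidueRecords).

    Real ubiquitin sequence on the idealized fold of
    :func:`_ub_calpha_trace`.  This is a constructed stand-in for the
    unavailable experimental monomer structure; see the module docstring.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    ca = _ub_calpha_trace()
    if jitter > 0:
        ca = ca + rng.normal(0.0, jitter, ca.shape)
    residues = []
    n = len(UBIQUITIN_SEQUENCE)
    for i, one in enumerate(UBIQUITIN_SEQUENCE, start=1):
        p = ca[i - 1]
        nxt = ca[min(i, n - 1)]
        prv = ca[max(i - 2, 0)]
        tangent = nxt - prv
        tnorm = np.linalg.norm(tangent)
        tangent = tangent / tnorm if tnorm > 1e-9 else np.array([0.0, 0.0, 1.0])
        sc_dir = _ub_sidechain_dir(i, ca)
        atoms = [
            ("N", "N", (p - 0.12 * tangent) * 10.0, 1.0, ""),
            ("CA", "C", p * 10.0, 1.0, ""),
            ("C", "C", (p + 0.12 * tangent) * 10.0, 1.0, ""),
        ]
        if one != "G":
            atoms.append(("CB", "C", (p + 0.17 * sc_dir) * 10.0, 1.0, ""))
            if one not in "ASTCV":
                atoms.append(("CG", "C", (p + 0.30 * sc_dir) * 10.0, 1.0, ""))
        residues.append(ResidueRecord("A", i, ONE_TO_THREE[one],
                                      [(nm, el, np.asarray(c), o, al)
                                       for nm, el, c, o, al in atoms]))
    return residues


@dataclass
class UbDimerSystem:
    model: BeadModel
    topology: CGTopology
    contacts: list
    hp_matrix: object


def ub_dimer_system(linkage: str = "free", seed: int = 0,
                    params: TopologyParams | None = None) -> UbDimerSystem:
    """Complete diUb system on the synthetic monomer: coarse-grained
    dimer, charges, native contacts, topology with the requested linkage,
    and the MJ-derived hydrophobic matrix."""
    residues = ub_monomer_residues(seed=seed)
    contacts = detect_native_contacts(residues)
    m_a = coarse_grain(residues, "distal")
    m_b = coarse_grain(residues, "proximal")
    # separate the two copies so the initial dimer is not overlapped
    for b in m_b.beads:
        b.position = b.position + np.array([4.0, 0.0, 0.0])
    model, topo = build_topology([m_a, m_b], linkage=linkage,
                                 contacts=contacts, params=params)
    assign_charges(model)
    model.source_id = f"synthetic-ub-dimer({linkage})"
    return UbDimerSystem(model, topo, contacts, build_hydrophobic_matrix())
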