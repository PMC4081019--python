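"""State classification, populations, thermodynamic decomposition and Kd.

The conformational space of a diUb is coarse-grained into three states —
open (no interface, large inter-monomer distance), closed (I44-I44
interface formed) and compact (any other well-formed interface) — with
the compact state subdivided into I36-I36, I36-I44 and other, according
to which hydrophobic patches meet across the interface.  Cutoffs sit at
the free-energy barrier tops of the corresponding patch-distance
profiles: 0.86 nm (I44-I44), 0.96 nm (I36-I36) and 0.93 nm (I36-I44);
open is d_com >= 3.2 nm (the same filter used for interfacial-contact
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, KB

__all__ = [
    "StateCutoffs", "StatePopulations", "ThermoProfile", "LoopEntropyParams",
    "STATES", "classify_frame", "classify_series", "state_populations",
    "entropy_enthalpy", "estimate_kd", "three_state_apparent", "loop_entropy",
]

STATES = ("open", "closed", "I36-I36", "I36-I44", "other")
COMPACT_SUBSTATES = ("I36-I36", "I36-I44", "other")


@dataclass(frozen=True)
class StateCutoffs:
    open_dcom: float = 3.2        # nm, on d_com
    closed_i44i44: float = 0.86   # nm, on d_I44I44
    i36i36: float = 0.96          # nm, on d_I36I36
    i36i44: float = 0.93          # nm, on d_I36I44


@dataclass
class StatePopulations:
    """Percent fractions with between-replica standard deviations."""

    fractions: dict               # state -> percent (mean over replicas)
    sd: dict                      # state -> percent SD across replicas
    n_replicas: int

    @property
    def open(self) -> float:
        return self.fractions["open"]

    @property
    def closed(self) -> float:
        return self.fractions["closed"]

    @property
    def compact(self) -> float:
        return sum(self.fractions[s] for s in COMPACT_SUBSTATES)


@dataclass
class ThermoProfile:
    centers: np.ndarray
    F: np.ndarray                 # k_B T units, NaN where unpopulated
    H: np.ndarray
    TS: np.ndarray
    rho_sf: float
    rho_hf: float
    counts: np.ndarray


@dataclass(frozen=True)
class LoopEntropyParams:
    n_residues: int = 152         # diUb chain length
    b: float = 3.8                # persistence length, Angstrom
    constraint_length: float = 4.0  # Angstrom
    m_contacts: int = 0           # constraints already present


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_frame(op, cutoffs: StateCutoffs = StateCutoffs()) -> str:
    """Assign one frame to a state by the mutually exclusive precedence
    open -> closed -> I36-I36 -> I36-I44 -> other."""
    for name in ("d_com", "d_i44i44", "d_i36i36", "d_i36i44"):
        if not hasattr(op, name) and not (isinstance(op, dict) and name in op):
            raise ValueError(f"missing order parameter {name!r}")
    get = (lambda n: op[n]) if isinstance(op, dict) else (lambda n: getattr(op, n))
    if get("d_com") >= cutoffs.open_dcom:
        return "open"
    if get("d_i44i44") <= cutoffs.closed_i44i44:
        return "closed"
    if (get("d_i36i36") <= cutoffs.i36i36
            and get("d_i36i44") > cutoffs.i36i44
            and get("d_i44i44") > cutoffs.closed_i44i44):
        return "I36-I36"
    if (get("d_i36i44") <= cutoffs.i36i44
            and get("d_i44i44") > cutoffs.closed_i44i44):
        return "I36-I44"
    return "other"


def classify_series(table: dict, cutoffs: StateCutoffs = StateCutoffs()):
    """Vectorised classification of an order-parameter table (dict of
    arrays, as from :func:`ensemble_analysis.order_param_table`)."""
    d_com = np.asarray(table["d_com"])
    d44 = np.asarray(table["d_i44i44"])
    d36 = np.asarray(table["d_i36i36"])
    d3644 = np.asarray(table["d_i36i44"])
    labels = np.full(d_com.shape, "other", dtype=object)
    is_open = d_com >= cutoffs.open_dcom
    is_closed = ~is_open & (d44 <= cutoffs.closed_i44i44)
    rest = ~is_open & ~is_closed
    is_3636 = rest & (d36 <= cutoffs.i36i36) & (d3644 > cutoffs.i36i44)
    is_3644 = rest & ~is_3636 & (d3644 <= cutoffs.i36i44)
    labels[is_open] = "open"
    labels[is_closed] = "closed"
    labels[is_3636] = "I36-I36"
    labels[is_3644] = "I36-I44"
    return labels


def state_populations(tables_per_replica: list,
                      cutoffs: StateCutoffs = StateCutoffs()) -> StatePopulations:
    """Percent state populations averaged over replicas, with SDs
    measured across the independent replicas."""
    if not tables_per_replica:
        raise ValueError("need at least one replica")
    per_rep = []
    for table in tables_per_replica:
        labels = classify_series(table, cutoffs)
        if labels.size == 0:
            raise ValueError("empty trajectory")
        per_rep.append({s: 100.0 * np.mean(labels == s) for s in STATES})
    fr = {s: float(np.mean([p[s] for p in per_rep])) for s in STATES}
    sd = {s: float(np.std([p[s] for p in per_rep], ddof=0)) for s in STATES}
    return StatePopulations(fractions=fr, sd=sd, n_replicas=len(per_rep))


# ---------------------------------------------------------------------------
# entropy-enthalpy decomposition
# ---------------------------------------------------------------------------

def entropy_enthalpy(x, energy, bins: int = 50, kbt: float = 1.0,
                     min_count: int = 10) -> ThermoProfile:
    """Bin-wise decomposition F(x) = H(x) - TS(x) along an order parameter.

    F(x) = -k_B T ln P(x) (shifted to min 0); H(x) is the mean potential
    energy conditioned on x (shifted by its populated-bin minimum so the
    two scales are comparable); TS = H - F by construction.  rho_SF and
    rho_HF are Pearson correlations of TS and H with F over bins holding
    at least ``min_count`` samples.
    """
    x = np.asarray(x, dtype=float)
    e = np.asarray(energy, dtype=float)
    if x.size == 0 or x.size != e.size:
        raise ValueError("series must be equal-length and non-empty")
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(x, edges) - 1, 0, bins - 1)
    H = np.full(bins, np.nan)
    for b in range(bins):
        sel = which == b
        if np.any(sel):
            H[b] = e[sel].mean()
    with np.errstate(divide="ignore"):
        F = -kbt * np.log(counts.astype(float))
    F[counts == 0] = np.nan
    F -= np.nanmin(F)
    H -= np.nanmin(H)
    TS = H - F
    good = counts >= min_count
    if good.sum() >= 3:
        rho_sf = float(np.corrcoef(TS[good], F[good])[0, 1])
        rho_hf = float(np.corrcoef(H[good], F[good])[0, 1])
    else:
        rho_sf = rho_hf = float("nan")
    return ThermoProfile(centers=centers, F=F, H=H, TS=TS,
                         rho_sf=rho_sf, rho_hf=rho_hf, counts=counts)


# ---------------------------------------------------------------------------
# dissociation constant
# ---------------------------------------------------------------------------

def estimate_kd(bound_fraction: float, box_volume_nm3: float,
                n_molecules: int = 2, convention: str = "pairwise"):
    """Dissociation constant (mol/L) from the bound fraction of an
    n-molecule periodic box.

    conventions (documented in the returned metadata):

    * ``pairwise`` (default): Kd = ((1-Pb)^2/Pb) * (n^2/(N_A V)) * (1/n)
    * ``mass_action``: Kd = [M]^2/[D] with [M] = n(1-Pb)/(N_A V) and
      [D] = n Pb/(2 N_A V), i.e. 2n(1-Pb)^2/(Pb N_A V)

    Pb = 0 or 1 yields a one-sided bound (inf / 0) flagged in metadata.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound fraction must lie in [0, 1]")
    v_litres = box_volume_nm3 * 1e-24
    meta = {"convention": convention, "n_molecules": n_molecules,
            "box_volume_nm3": box_volume_nm3, "bound": False}
    if bound_fraction == 0.0:
        meta["bound"] = "lower"
        return float("inf"), meta
    if bound_fraction == 1.0:
        meta["bound"] = "upper"
        return 0.0, meta
    pb = bound_fraction
    if convention == "pairwise":
        kd = ((1 - pb) ** 2 / pb) * (n_molecules**2 / (AVOGADRO * v_litres)) / n_molecules
    elif convention == "mass_action":
        kd = 2.0 * n_molecules * (1 - pb) ** 2 / (pb * AVOGADRO * v_litres)
    else:
        raise ValueError(f"unknown Kd convention {convention!r}")
    return float(kd), meta


# ---------------------------------------------------------------------------
# three-state reconciliation of two-state readouts
# ---------------------------------------------------------------------------

def three_state_apparent(open_f: float, closed_f: float, compact_f: float) -> dict:
    """Apparent two-state readouts implied by a three-state system.

    A closed-referenced experiment (closed vs everything else) reports
    apparent open = 1 - closed; an open-referenced experiment reports
    apparent closed = 1 - open.  Both inflate their reported fraction by
    the compact population, which reconciles seemingly contradictory
    two-state estimates.
    """
    fr = np.array([open_f, closed_f, compact_f], dtype=float)
    if np.any(fr < 0):
        raise ValueError("negative fractions")
    if not np.isclose(fr.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must sum to 1")
    return {
        "true": {"open": open_f, "closed": closed_f, "compact": compact_f},
        "apparent_open_closed_referenced": 1.0 - closed_f,
        "apparent_closed_open_referenced": 1.0 - open_f,
    }


# ---------------------------------------------------------------------------
# polymer-theory constraint entropy
# ---------------------------------------------------------------------------

def loop_entropy(params: LoopEntropyParams = LoopEntropyParams()) -> dict:
    """Entropy change of forming one loop-closure constraint, from the
    Gaussian-chain closure probability

        P = (3 / (2 pi N_eff b^2))^{3/2} * (4 pi / 3) I^3,

    with N_eff = N/(m+1) (constraints already present shorten the
    effective chain).  Returns P and Delta S = k_B ln P (in k_B units).
    """
    n_eff = params.n_residues / (params.m_contacts + 1)
    b, ell = params.b, params.constraint_length
    p = (3.0 / (2.0 * np.pi * n_eff * b * b)) ** 1.5 * (4.0 * np.pi / 3.0) * ell**3
    return {"probability": float(p), "delta_s_kb": float(np.log(p)),
            "n_eff": float(n_eff)}
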