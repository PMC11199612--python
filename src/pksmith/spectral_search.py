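"""Candidate-to-spectrum matching with target-decoy FDR.

Candidate molecules are matched to tandem mass spectra by in-silico
fragmentation: round 1 removes one acyclic single bond, or any two bonds of
one ring; round 2 applies the same operator to every round-1 fragment.  The
match score is the shared-peak count — the number of spectrum peaks within a
fragment tolerance of any singly-protonated fragment m/z ([M+H]+ adducts,
positive mode).  Exact search requires the precursor neutral mass to match
the molecule; variable search tolerates one unknown mass offset (an
unpredicted starter unit or modification), applied to every fragment or, when
the candidate declares an attachment atom, only to fragments containing it.

False discovery rates use a target-decoy scheme: decoys are generated by a
fixed number of edge-switching steps on the molecular multigraph (swap the
endpoints of two bonds, keeping the graph connected and chemically valid and
preserving each atom's bond-order total), rejecting decoys whose InChIKey
appears in the target set.  FDR at a score threshold is N_decoy / N_target.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml
from rdkit import Chem
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276
DEFAULT_FRAG_TOL = 0.02
DEFAULT_PREC_TOL = 0.02
DEFAULT_MAX_SHIFT = 400.0
DEFAULT_MIN_REL_INTENSITY = 0.01
DEFAULT_DECOY_STEPS = 25


class SpectralError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    identifier: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.mz, kind="stable")
        self.mz = np.asarray(self.mz, dtype=float)[order]
        self.intensity = np.asarray(self.intensity, dtype=float)[order]
        if self.charge < 1:
            raise SpectralError(f"spectrum {self.identifier}: charge must be >= 1")

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON_MASS

    def filtered(self, min_rel_intensity: float) -> "Spectrum":
        """Drop peaks below a relative-intensity floor (noise control)."""
        if self.intensity.size == 0 or min_rel_intensity <= 0:
            return self
        keep = self.intensity >= min_rel_intensity * self.intensity.max()
        return Spectrum(
            identifier=self.identifier,
            precursor_mz=self.precursor_mz,
            charge=self.charge,
            mz=self.mz[keep],
            intensity=self.intensity[keep],
        )


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read MGF or mzML; peaks are sorted, absent charges default to 1."""
    path = str(path)
    spectra: list[Spectrum] = []
    if path.lower().endswith(".mgf"):
        with _mgf.MGF(path) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params:
                    warnings.warn(f"spectrum {i}: missing precursor; skipped")
                    continue
                charge = params.get("charge")
                if charge is None:
                    logger.info("spectrum %d: no charge; defaulting to 1", i)
                    z = 1
                else:
                    z = abs(int(charge[0]))
                spectra.append(
                    Spectrum(
                        identifier=str(params.get("title", f"scan{i}")),
                        precursor_mz=float(params["pepmass"][0]),
                        charge=z,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    elif path.lower().endswith(".mzml"):
        with _mzml.MzML(path) as reader:
            for i, entry in enumerate(reader):
                try:
                    precursor = entry["precursorList"]["precursor"][0][
                        "selectedIonList"]["selectedIon"][0]
                except (KeyError, IndexError):
                    warnings.warn(f"spectrum {i}: missing precursor; skipped")
                    continue
                z = int(precursor.get("charge state", 1))
                spectra.append(
                    Spectrum(
                        identifier=entry.get("id", f"scan{i}"),
                        precursor_mz=float(precursor["selected ion m/z"]),
                        charge=z,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    else:
        raise SpectralError(f"unsupported spectrum format: {path}")
    if not spectra:
        raise SpectralError(f"{path}: no usable spectra")
    return spectra


# ---------------------------------------------------------------------------
# In-silico fragmentation
# ---------------------------------------------------------------------------

@dataclass
class FragmentSet:
    masses: np.ndarray  # sorted, deduplicated (1e-6 Da)
    depth: dict[float, int] = field(default_factory=dict)
    #: per fragment mass: does the fragment contain the attachment atom
    contains_attachment: np.ndarray | None = None


def _atom_masses(mol: Chem.Mol) -> np.ndarray:
    pt = Chem.GetPeriodicTable()
    out = np.zeros(mol.GetNumAtoms())
    h = pt.GetMostCommonIsotopeMass(1)
    for atom in mol.GetAtoms():
        out[atom.GetIdx()] = (
            pt.GetMostCommonIsotopeMass(atom.GetAtomicNum())
            + atom.GetTotalNumHs() * h
        )
    return out


def _cut_once(graph: nx.Graph, nodes: frozenset) -> list[frozenset]:
    """All sub-fragments from one round of cutting on an atom subset.

    Cuts: one acyclic (bridge) single bond, or any two bonds of one ring
    (a non-bridge bond plus any bond that co-disconnects with it).
    """
    sub = graph.subgraph(nodes)
    pieces: list[frozenset] = []
    bridges = set(frozenset(e) for e in nx.bridges(sub))
    edges = list(sub.edges(data=True))
    for u, v, data in edges:
        if frozenset((u, v)) in bridges:
            if data["order"] != 1.0:
                continue  # acyclic cuts act on single bonds only
            g2 = sub.copy()
            g2.remove_edge(u, v)
            pieces.extend(frozenset(c) for c in nx.connected_components(g2))
    # ring cuts: unordered pairs of (non-bridge) ring bonds whose joint
    # removal disconnects the fragment — i.e. two bonds of one ring
    non_bridge = [
        (u, v) for u, v, _ in edges if frozenset((u, v)) not in bridges
    ]
    for (u1, v1), (u2, v2) in itertools.combinations(non_bridge, 2):
        g2 = sub.copy()
        g2.remove_edge(u1, v1)
        g2.remove_edge(u2, v2)
        comps = list(nx.connected_components(g2))
        if len(comps) == 2:
            pieces.extend(frozenset(c) for c in comps)
    return pieces


def fragment(
    molecule: Chem.Mol, depth: int = 2, attachment_atom: int | None = None
) -> FragmentSet:
    """Fragment masses from one or two rounds of bond cutting.

    The parent mass is always present (zero cuts).  Masses are monoisotopic
    (each heavy atom plus its hydrogens; no hydrogen rearrangement) and
    deduplicated within 1e-6 Da.  If ``attachment_atom`` is given (or the
    molecule carries an ``attachment`` atom property), each retained mass
    records whether some generating fragment contains that atom, for
    mass-shift attribution in variable search.
    """
    if depth not in (1, 2):
        raise SpectralError("fragmentation depth must be 1 or 2")
    mol = Chem.Mol(molecule)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    if attachment_atom is None:
        for atom in mol.GetAtoms():
            if atom.HasProp("attachment"):
                attachment_atom = atom.GetIdx()
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        graph.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
            order=bond.GetBondTypeAsDouble(),
        )
    masses = _atom_masses(mol)
    whole = frozenset(range(mol.GetNumAtoms()))
    level0 = {whole}
    level1 = set(_cut_once(graph, whole))
    frags: dict[frozenset, int] = {whole: 0}
    for f in level1:
        frags.setdefault(f, 1)
    if depth == 2:
        for f in level1:
            if len(f) < 2:
                continue
            for f2 in _cut_once(graph, f):
                frags.setdefault(f2, 2)
    entries = []
    for f, d in frags.items():
        m = float(masses[list(f)].sum())
        entries.append((m, d, attachment_atom in f if attachment_atom is not None else True))
    entries.sort()
    out_m: list[float] = []
    out_d: dict[float, int] = {}
    out_a: list[bool] = []
    for m, d, has_att in entries:
        if out_m and m - out_m[-1] < 1e-6:
            out_a[-1] = out_a[-1] or has_att
            out_d[out_m[-1]] = min(out_d[out_m[-1]], d)
            continue
        out_m.append(m)
        out_d[m] = d
        out_a.append(has_att)
    return FragmentSet(
        masses=np.array(out_m),
        depth=out_d,
        contains_attachment=np.array(out_a, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class CompoundSpectrumMatch:
    compound_id: str
    spectrum_id: str
    score: int
    shift: float = 0.0
    matched_peaks: list[float] = field(default_factory=list)


def _count_matched_peaks(
    peaks: np.ndarray, frag_mz: np.ndarray, frag_tol: float
) -> tuple[int, list[float]]:
    if peaks.size == 0 or frag_mz.size == 0:
        return 0, []
    frag_mz = np.sort(frag_mz)
    idx = np.searchsorted(frag_mz, peaks)
    lo = np.clip(idx - 1, 0, frag_mz.size - 1)
    hi = np.clip(idx, 0, frag_mz.size - 1)
    near = np.minimum(
        np.abs(peaks - frag_mz[lo]), np.abs(peaks - frag_mz[hi])
    )
    hit = near <= frag_tol
    return int(hit.sum()), [float(p) for p in peaks[hit]]


def score_exact(
    molecule: Chem.Mol,
    spectrum: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    prec_tol: float = DEFAULT_PREC_TOL,
    depth: int = 2,
    compound_id: str = "",
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
    fragments: FragmentSet | None = None,
) -> CompoundSpectrumMatch | None:
    """Shared-peak-count match, gated on precursor mass agreement.

    Returns None when |precursor neutral mass - molecule mass| > prec_tol.
    Score = number of (intensity-filtered) peaks within ``frag_tol`` of any
    singly-protonated fragment m/z; each peak counts at most once.
    """
    if frag_tol <= 0 or prec_tol <= 0:
        raise SpectralError("tolerances must be positive")
    mass = Descriptors.ExactMolWt(molecule)
    if abs(spectrum.precursor_neutral_mass - mass) > prec_tol:
        return None
    if fragments is None:
        fragments = fragment(molecule, depth)
    spec = spectrum.filtered(min_rel_intensity)
    score, matched = _count_matched_peaks(
        spec.mz, fragments.masses + PROTON_MASS, frag_tol
    )
    return CompoundSpectrumMatch(
        compound_id=compound_id,
        spectrum_id=spectrum.identifier,
        score=score,
        shift=0.0,
        matched_peaks=matched,
    )


def score_variable(
    molecule: Chem.Mol,
    spectrum: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    max_shift: float = DEFAULT_MAX_SHIFT,
    prec_tol: float = DEFAULT_PREC_TOL,
    depth: int = 2,
    compound_id: str = "",
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
    fragments: FragmentSet | None = None,
) -> CompoundSpectrumMatch | None:
    """Mass-shift-tolerant match (unknown starter unit or modification).

    The offset D = precursor neutral mass - molecule mass is accepted when
    |D| <= max_shift (or |D| <= prec_tol, the exact-match window, in which
    case D is treated as 0); each fragment may then match at m/z f or f + D.
    When the candidate declares an attachment atom, D applies only to
    fragments containing it.  With max_shift = 0 this reduces exactly to
    :func:`score_exact`.
    """
    if frag_tol <= 0:
        raise SpectralError("tolerances must be positive")
    mass = Descriptors.ExactMolWt(molecule)
    delta = spectrum.precursor_neutral_mass - mass
    if abs(delta) <= prec_tol:
        delta = 0.0
    elif abs(delta) > max_shift:
        return None
    if fragments is None:
        fragments = fragment(molecule, depth)
    spec = spectrum.filtered(min_rel_intensity)
    base = fragments.masses + PROTON_MASS
    if delta == 0.0:
        frag_mz = base
    else:
        if fragments.contains_attachment is not None:
            shiftable = base[fragments.contains_attachment] + delta
        else:
            shiftable = base + delta
        frag_mz = np.concatenate([base, shiftable])
    score, matched = _count_matched_peaks(spec.mz, frag_mz, frag_tol)
    return CompoundSpectrumMatch(
        compound_id=compound_id,
        spectrum_id=spectrum.identifier,
        score=score,
        shift=float(delta),
        matched_peaks=matched,
    )


# ---------------------------------------------------------------------------
# Edge-switching decoys
# ---------------------------------------------------------------------------

def _try_switch(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    """One edge switch: pick bonds (a-b, c-d) with 4 distinct atoms and swap
    endpoints (a-d, c-b), each bond keeping its order.  Reject switches that
    create duplicate bonds, break connectivity, or fail sanitization."""
    bonds = list(rw.GetBonds())
    if len(bonds) < 2:
        return False
    i, j = rng.choice(len(bonds), size=2, replace=False)
    b1, b2 = bonds[int(i)], bonds[int(j)]
    a, b = b1.GetBeginAtomIdx(), b1.GetEndAtomIdx()
    c, d = b2.GetBeginAtomIdx(), b2.GetEndAtomIdx()
    if rng.integers(2):
        c, d = d, c
    if len({a, b, c, d}) != 4:
        return False
    o1, o2 = b1.GetBondType(), b2.GetBondType()
    if rw.GetBondBetweenAtoms(a, d) or rw.GetBondBetweenAtoms(c, b):
        return False
    probe = Chem.RWMol(rw)
    probe.RemoveBond(a, b)
    probe.RemoveBond(c, d)
    probe.AddBond(a, d, o1)
    probe.AddBond(c, b, o2)
    mol = probe.GetMol()
    if len(Chem.GetMolFrags(mol)) != 1:
        return False
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return False
    rw.RemoveBond(a, b)
    rw.RemoveBond(c, d)
    rw.AddBond(a, d, o1)
    rw.AddBond(c, b, o2)
    return True


def generate_decoy(
    molecule: Chem.Mol,
    steps: int = DEFAULT_DECOY_STEPS,
    seed: int = 0,
    targets: set[str] | None = None,
    max_step_retries: int = 100,
    max_regenerations: int = 20,
) -> Chem.Mol:
    """Decoy by ``steps`` edge-switching operations on the bond multigraph.

    Each accepted switch preserves the heavy-atom composition and every
    atom's bond-order total, keeps the molecule connected, and must
    sanitize.  A decoy whose InChIKey appears in ``targets`` is rejected and
    regenerated from a fresh seed stream.
    """
    if molecule.GetNumBonds() < 2:
        raise SpectralError("molecule has fewer than 2 bonds; cannot switch edges")
    targets = targets or set()
    for regen in range(max_regenerations):
        rng = np.random.default_rng((seed, regen))
        rw = Chem.RWMol(molecule)
        Chem.Kekulize(rw, clearAromaticFlags=True)
        ok = True
        for _step in range(steps):
            for _try in range(max_step_retries):
                if _try_switch(rw, rng):
                    break
            else:
                logger.debug("step %d: no valid switch found; skipped", _step)
        decoy = rw.GetMol()
        try:
            Chem.SanitizeMol(decoy)
        except Exception:
            ok = False
        if ok:
            if steps == 0 or Chem.MolToInchiKey(decoy) not in targets:
                return decoy
    raise SpectralError("decoy generation retry budget exhausted")


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    n_decoy: int
    n_target: int
    threshold: float
    fdr: float
    defined: bool = True


def estimate_fdr(
    target_matches: list[CompoundSpectrumMatch],
    decoy_matches: list[CompoundSpectrumMatch],
    threshold: float,
) -> FdrResult:
    """Target-decoy FDR at a score threshold: N_decoy / N_target."""
    n_t = sum(1 for m in target_matches if m.score >= threshold)
    n_d = sum(1 for m in decoy_matches if m.score >= threshold)
    if n_t == 0:
        return FdrResult(
            n_decoy=n_d, n_target=0, threshold=threshold,
            fdr=float("nan"), defined=False,
        )
    return FdrResult(
        n_decoy=n_d, n_target=n_t, threshold=threshold, fdr=n_d / n_t
    )
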