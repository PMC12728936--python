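"""Molecule curation, torsion matching, and histogram accumulation.

The extraction pipeline turns conformer ensembles into torsion-motif
torsional-angle distributions (tmTADs):

1. curate each structure (split multi-molecule entries, complete hydrogens,
   element whitelist, require a C-C bond);
2. assign each acyclic single bond to the first library pattern that
   matches it, recording *all* atom mappings of that pattern on that bond;
3. prune computed ensembles at a relative potential-energy cutoff;
4. measure dihedrals, mirror-augment (record both theta and 360-theta,
   since an unmapped-stereochemistry SMARTS matches both enantiomers of a
   structure and the mirror image has identical energy);
5. accumulate counts on a uniform periodic grid over [0, 360) degrees.

Crystal-environment ensembles carry the observed conformer(s) only and
bypass energy pruning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

from .library import TorsionLibrary

logger = logging.getLogger(__name__)

#: Elements allowed in curated molecules.
ELEMENT_WHITELIST = frozenset({1, 6, 7, 8, 9, 15, 16, 17, 35, 53})  # H C N O F P S Cl Br I

ENVIRONMENTS = ("crystal", "vacuum", "water", "hexane", "other")


class CurationError(ValueError):
    """Raised when a structure entry cannot be parsed at all."""


class DihedralError(ValueError):
    """Raised when a dihedral is undefined (collinear atoms)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A curated single molecule with explicit hydrogens."""

    mol: Chem.Mol
    identifier: str
    provenance: str = "computed"  # "crystal" | "computed"


@dataclass(frozen=True)
class CurationReport:
    identifier: str
    n_components: int
    kept: tuple[str, ...]
    dropped: tuple[tuple[str, str], ...]  # (component id, reason)


@dataclass
class ConformerEnsemble:
    """All conformers of one molecule in one environment.

    ``conformers`` holds ``(coordinates, energy)`` pairs; coordinates are
    (n_atoms, 3) arrays in Angstrom, energies are potential energies in
    kJ/mol (``None`` for crystal-observed conformers, which carry no
    computed energy).
    """

    molecule: MoleculeRecord
    conformers: list[tuple[np.ndarray, float | None]]
    environment: str = "other"

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        for _, e in self.conformers:
            if e is not None and not np.isfinite(e):
                raise ValueError("conformer energies must be finite")


@dataclass(frozen=True)
class TorsionMatch:
    """One central bond assigned to one pattern, with every atom mapping."""

    pattern_id: str
    central_bond: tuple[int, int]
    mappings: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        bond = frozenset(self.central_bond)
        if not self.mappings:
            raise ValueError("a TorsionMatch needs at least one mapping")
        for q in self.mappings:
            if frozenset(q[1:3]) != bond:
                raise ValueError(f"mapping {q} does not straddle bond {self.central_bond}")


@dataclass
class TorsionHistogram:
    """Accumulated angle counts on a uniform partition of [0, 360) degrees."""

    pattern_id: str
    environment: str
    counts: np.ndarray
    augmented: bool = False

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.n_bins + 1)

    @property
    def bin_centers_deg(self) -> np.ndarray:
        w = 360.0 / self.n_bins
        return (np.arange(self.n_bins) + 0.5) * w

    def mirror_bin(self, b: int) -> int:
        """Bin paired with ``b`` under theta -> 360 - theta (k <-> n-1-k)."""
        return self.n_bins - 1 - b


# -- curation -----------------------------------------------------------------

def curate_molecule(
    entry: Chem.Mol | str,
    identifier: str = "entry",
    provenance: str = "computed",
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Split an entry into single molecules and apply the curation filters.

    Accepts an RDKit molecule or a MOL-block string.  Each connected
    component becomes its own candidate record; hydrogens are completed
    explicitly.  Components containing elements outside the whitelist
    (H, C, N, O, F, Cl, Br, I, S, P) or lacking a carbon-carbon bond are
    dropped, with the reason recorded in the report.
    """
    if isinstance(entry, str):
        mol = Chem.MolFromMolBlock(entry, removeHs=False)
        if mol is None:
            raise CurationError(f"entry {identifier!r}: structure does not parse")
    elif isinstance(entry, Chem.Mol):
        mol = entry
    else:
        raise CurationError(f"entry {identifier!r}: unsupported input type")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    kept: list[MoleculeRecord] = []
    dropped: list[tuple[str, str]] = []
    for i, frag in enumerate(frags):
        cid = identifier if len(frags) == 1 else f"{identifier}.{i}"
        has_conf = frag.GetNumConformers() > 0
        fragH = Chem.AddHs(frag, addCoords=has_conf)
        elems = {a.GetAtomicNum() for a in fragH.GetAtoms()}
        bad = elems - ELEMENT_WHITELIST
        if bad:
            symbols = sorted(Chem.GetPeriodicTable().GetElementSymbol(z) for z in bad)
            dropped.append((cid, f"disallowed elements: {', '.join(symbols)}"))
            continue
        has_cc = any(
            b.GetBeginAtom().GetAtomicNum() == 6 and b.GetEndAtom().GetAtomicNum() == 6
            for b in fragH.GetBonds()
        )
        if not has_cc:
            dropped.append((cid, "no carbon-carbon bond"))
            continue
        kept.append(MoleculeRecord(fragH, cid, provenance))
    report = CurationReport(identifier, len(frags), tuple(r.identifier for r in kept), tuple(dropped))
    return kept, report


# -- matching -----------------------------------------------------------------

def match_torsions(record: MoleculeRecord, library: TorsionLibrary) -> list[TorsionMatch]:
    """Assign every matching central bond to its first-matching pattern.

    Patterns are tried in hierarchy order.  A bond claimed by an earlier
    pattern is invisible to later ones; for the claiming pattern, every
    distinct atom mapping onto that bond is recorded, so symmetric motifs
    contribute one angle per mapping rather than a single arbitrary
    representative.
    """
    mol = record.mol
    assigned: dict[frozenset[int], TorsionMatch] = {}
    order: list[frozenset[int]] = []
    for pattern in library:
        idx = pattern.map_indices()
        qpos = (idx[1], idx[2], idx[3], idx[4])
        matches = mol.GetSubstructMatches(pattern.query, uniquify=False, maxMatches=100000)
        if not matches:
            continue
        per_bond: dict[frozenset[int], set[tuple[int, int, int, int]]] = {}
        for m in matches:
            quad = tuple(m[q] for q in qpos)
            bond = frozenset(quad[1:3])
            if bond in assigned:
                continue  # claimed by a higher-priority pattern
            per_bond.setdefault(bond, set()).add(quad)
        for bond, quads in per_bond.items():
            j, k = sorted(bond)
            assigned[bond] = TorsionMatch(pattern.pattern_id, (j, k), tuple(sorted(quads)))
            order.append(bond)
    return [assigned[b] for b in order]


# -- geometry -----------------------------------------------------------------

def measure_dihedral(coords: np.ndarray, quad: Sequence[int]) -> float:
    """Signed dihedral for atoms ``(i, j, k, l)``, mapped into [0, 360) degrees.

    Uses the standard convention: looking down the j->k bond, the angle from
    the i-j-k plane to the j-k-l plane, positive clockwise.  Reversing the
    quadruple gives the same value; mirror-image coordinates give
    ``(360 - theta) mod 360``.
    """
    i, j, k, l = quad
    if len({i, j, k, l}) != 4:
        raise DihedralError(f"quadruple {quad} has repeated atoms")
    p = np.asarray(coords, dtype=float)
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(1.0, np.linalg.norm(b1) * nb2) or \
       np.linalg.norm(n2) < 1e-10 * max(1.0, np.linalg.norm(b3) * nb2):
        raise DihedralError(f"dihedral undefined for quadruple {quad}: collinear atoms")
    theta = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    return float(theta % 360.0)


# -- ensemble processing ------------------------------------------------------

def prune_by_energy(ensemble: ConformerEnsemble, cutoff_kjmol: float = 25.0) -> ConformerEnsemble:
    """Keep conformers within ``cutoff_kjmol`` of the ensemble minimum energy.

    The minimum-energy conformer is always retained (cutoff 0 keeps exactly
    the minimum-energy conformer or conformers).  Crystal ensembles carry no
    energies and are returned unchanged.
    """
    energies = [e for _, e in ensemble.conformers]
    if any(e is None for e in energies):
        if ensemble.environment == "crystal" or all(e is None for e in energies):
            return ensemble
        raise ValueError("computed ensemble has conformers without energies")
    emin = min(energies)
    kept = [(c, e) for c, e in ensemble.conformers if e - emin <= cutoff_kjmol]
    return ConformerEnsemble(ensemble.molecule, kept, ensemble.environment)


def augment_mirror(angles: Iterable[float]) -> list[float]:
    """Mirror-augment a list of angles: each theta yields theta and
    ``(360 - theta) mod 360``.

    A SMARTS motif carries no stereochemistry, so it matches a structure and
    its mirror image alike; the mirror image is isoenergetic, hence an
    observed 10 degrees contributes both 10 and 350 degrees.
    """
    out: list[float] = []
    for a in angles:
        a = float(a)
        out.append(a)
        out.append((360.0 - a) % 360.0)
    return out


def accumulate(
    angles: Iterable[float],
    n_bins: int = 360,
    pattern_id: str = "",
    environment: str = "other",
    augmented: bool = False,
) -> TorsionHistogram:
    """Bin angles on a uniform half-open partition of [0, 360) degrees.

    Bin k covers [k*w, (k+1)*w) with w = 360/n_bins; an angle exactly on an
    edge belongs to the bin to its right.  Angles outside [0, 360) are
    wrapped with a warning.
    """
    if n_bins < 2 or 360 % n_bins != 0:
        raise ValueError("n_bins must be >= 2 and divide 360 evenly")
    arr = np.asarray(list(angles), dtype=float)
    counts = np.zeros(n_bins, dtype=np.int64)
    if arr.size:
        if np.any((arr < 0.0) | (arr >= 360.0)):
            warnings.warn("angles outside [0, 360) wrapped modulo 360", stacklevel=2)
            arr = np.mod(arr, 360.0)
        idx = np.floor(arr * n_bins / 360.0).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return TorsionHistogram(pattern_id, environment, counts, augmented)


def extract_ensemble(
    ensemble: ConformerEnsemble,
    library: TorsionLibrary,
    cutoff_kjmol: float = 25.0,
    n_bins: int = 360,
    augment: bool = True,
) -> dict[str, TorsionHistogram]:
    """Run the full per-ensemble pipeline; one histogram per matched pattern."""
    pruned = prune_by_energy(ensemble, cutoff_kjmol)
    matches = match_torsions(pruned.molecule, library)
    out: dict[str, TorsionHistogram] = {}
    for match in matches:
        angles: list[float] = []
        for coords, _ in pruned.conformers:
            for quad in match.mappings:
                angles.append(measure_dihedral(coords, quad))
        if augment:
            angles = augment_mirror(angles)
        hist = accumulate(angles, n_bins, match.pattern_id, pruned.environment, augment)
        if match.pattern_id in out:
            out[match.pattern_id].counts += hist.counts
        else:
            out[match.pattern_id] = hist
    return out


def accumulate_ensembles(
    ensembles: Iterable[ConformerEnsemble],
    library: TorsionLibrary,
    cutoff_kjmol: float = 25.0,
    n_bins: int = 360,
    augment: bool = True,
) -> dict[tuple[str, str], TorsionHistogram]:
    """Accumulate tmTADs over many ensembles, keyed by (pattern, environment)."""
    out: dict[tuple[str, str], TorsionHistogram] = {}
    for ens in ensembles:
        for pid, hist in extract_ensemble(ens, library, cutoff_kjmol, n_bins, augment).items():
            key = (pid, ens.environment)
            if key in out:
                out[key].counts += hist.counts
            else:
                out[key] = hist
    return out


# -- SDF input ----------------------------------------------------------------

def read_sdf_ensembles(
    path: str | Path,
    energy_prop: str = "E_kJ_mol",
    environment: str = "other",
    provenance: str = "computed",
) -> list[ConformerEnsemble]:
    """Read conformer ensembles from a multi-record SDF.

    Consecutive records with identical connectivity (canonical SMILES) form
    one ensemble; each record contributes one conformer whose potential
    energy is read from the SDF property ``energy_prop`` (kJ/mol).  Records
    without that property get ``energy=None`` (allowed for crystal input).
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    ensembles: list[ConformerEnsemble] = []
    cur_smiles: str | None = None
    cur_mol: Chem.Mol | None = None
    cur_confs: list[tuple[np.ndarray, float | None]] = []
    cur_name = ""

    def flush() -> None:
        nonlocal cur_confs, cur_mol
        if cur_mol is not None and cur_confs:
            records, report = curate_molecule(cur_mol, cur_name, provenance)
            if len(records) != 1:
                for cid, reason in report.dropped:
                    logger.info("dropped %s: %s", cid, reason)
            if len(records) == 1 and records[0].mol.GetNumAtoms() == cur_mol.GetNumAtoms():
                ensembles.append(ConformerEnsemble(records[0], list(cur_confs), environment))
            elif records:
                logger.warning(
                    "entry %s: multi-component or H-incomplete SDF record; skipped", cur_name
                )
        cur_confs = []

    for i, mol in enumerate(supplier):
        if mol is None:
            raise CurationError(f"{path}: record {i} does not parse")
        smiles = Chem.MolToSmiles(mol)
        if smiles != cur_smiles:
            flush()
            cur_smiles = smiles
            cur_mol = mol
            cur_name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        energy = float(mol.GetProp(energy_prop)) if mol.HasProp(energy_prop) else None
        cur_confs.append((np.array(mol.GetConformer().GetPositions(), dtype=float), energy))
    flush()
    return ensembles
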