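"""Synthetic fixtures: angle samples from known mixtures, diagnostic
scenario pairs, and toy molecules matching the bundled SMARTS motifs.

Everything here is generated from fixed, documented parameters so that
every pipeline stage can be tested offline.  The scenario parameters are
fixture constants invented for this package (chosen to produce the four
qualitative relationships of interest), NOT values taken from any external
data set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .distances import AngleSample
from .extraction import MoleculeRecord, curate_molecule
from .fitting import FitParameters, evaluate_model

TWO_PI = 2.0 * np.pi

#: Grid size for inverse-CDF sampling (documented design choice: fine
#: enough that the piecewise-linear CDF error is far below sampling noise).
SAMPLING_GRID = 4096

SCENARIO_NAMES = ("same_distribution", "peak_split", "peak_broadening", "height_reversal")


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating parameters for one two-sided diagnostic scenario."""

    name: str
    params_a: FitParameters
    params_b: FitParameters
    n: int
    seed: int


def sample_angles(
    params: FitParameters,
    n: int,
    seed: int,
    pattern_id: str = "synthetic",
    environment: str = "other",
) -> AngleSample:
    """Draw ``n`` angles (degrees) from the normalized model density.

    Uses inverse-CDF sampling on a ``SAMPLING_GRID``-point grid over
    [0, 2*pi): the model density is integrated to a piecewise-linear CDF
    and uniform draws are interpolated through its inverse.  Deterministic
    given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    edges = np.linspace(0.0, TWO_PI, SAMPLING_GRID + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = evaluate_model(params, centers)
    total = pdf.sum()
    if total <= 0:
        raise ValueError("model density is identically zero (all amplitudes zero?)")
    cdf = np.concatenate([[0.0], np.cumsum(pdf) / total])
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    theta = np.interp(u, cdf, edges)
    return AngleSample(np.degrees(theta) % 360.0, environment, pattern_id)


def model_cdf(params: FitParameters, theta: np.ndarray) -> np.ndarray:
    """CDF of the normalized model density at ``theta`` (radians), on the
    same grid discretization used by :func:`sample_angles`."""
    edges = np.linspace(0.0, TWO_PI, SAMPLING_GRID + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = evaluate_model(params, centers)
    cdf = np.concatenate([[0.0], np.cumsum(pdf) / pdf.sum()])
    return np.interp(np.asarray(theta, dtype=float), edges, cdf)


def _deg(b: float) -> float:
    return float(np.radians(b))


def make_scenarios(seed: int = 0, n: int = 2000) -> dict[str, tuple[AngleSample, AngleSample]]:
    """The four diagnostic scenario pairs.

    * ``same_distribution``: two independent draws from one two-peak model;
    * ``peak_split``: one peak versus the same mass split into two nearby
      peaks straddling the original location;
    * ``peak_broadening``: the base model versus the same peaks twice as wide;
    * ``height_reversal``: two peaks with amplitudes (1.0, 0.5) versus
      (0.5, 1.0).

    All generating parameters are synthetic fixture constants.
    """
    specs = list(scenario_specs(seed, n))
    out: dict[str, tuple[AngleSample, AngleSample]] = {}
    for spec in specs:
        sa = sample_angles(spec.params_a, spec.n, spec.seed, spec.name, "side_a")
        sb = sample_angles(spec.params_b, spec.n, spec.seed + 1, spec.name, "side_b")
        out[spec.name] = (sa, sb)
    return out


def scenario_specs(seed: int = 0, n: int = 2000) -> list[ScenarioSpec]:
    base = FitParameters([(1.0, _deg(60), 0.30), (0.6, _deg(160), 0.25)])
    broad = FitParameters([(1.0, _deg(60), 0.60), (0.6, _deg(160), 0.50)])
    single = FitParameters([(1.0, _deg(90), 0.25)])
    split = FitParameters([(0.5, _deg(75), 0.25), (0.5, _deg(105), 0.25)])
    rev_a = FitParameters([(1.0, _deg(60), 0.30), (0.5, _deg(160), 0.30)])
    rev_b = FitParameters([(0.5, _deg(60), 0.30), (1.0, _deg(160), 0.30)])
    return [
        ScenarioSpec("same_distribution", base, base, n, seed),
        ScenarioSpec("peak_split", single, split, n, seed + 100),
        ScenarioSpec("peak_broadening", base, broad, n, seed + 200),
        ScenarioSpec("height_reversal", rev_a, rev_b, n, seed + 300),
    ]


# -- toy molecules ------------------------------------------------------------

#: (SMILES, expected pattern_id from the bundled fixture library, description)
TOY_MOLECULES: tuple[tuple[str, str | None, str], ...] = (
    ("CC(C)=C(C)C(C)=C", "diene_cc", "permethylated 1,3-diene (conjugated ene-ene single bond)"),
    ("CNC(=O)c1ccccc1F", "fbenzamide_cc", "2-fluoro-N-methylbenzamide"),
    ("COc1ccccc1O", "arylether_co", "2-methoxyphenol (aryl methyl ether with ortho-OH)"),
    ("c1ccccc1", None, "benzene: no acyclic single bond, matches nothing"),
    ("C=CC=C", None, "butadiene: terminal CH2 groups fail the CX3H0 requirement"),
)


def make_toy_molecules() -> list[tuple[MoleculeRecord, str | None]]:
    """Small molecules built to exercise the bundled fixture patterns.

    Returns curated records paired with the pattern id their *highest
    priority* central-bond match should carry (``None`` for negative
    controls that must not match the three published motifs).
    """
    out = []
    for smiles, expected, _ in TOY_MOLECULES:
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        records, _report = curate_molecule(mol, identifier=smiles)
        if not records:  # benzene-style controls still pass curation (C-C bonds)
            raise RuntimeError(f"toy molecule {smiles} unexpectedly failed curation")
        out.append((records[0], expected))
    return out


def make_toy_sdf(path: str, seed: int = 0, n_confs: int = 5) -> int:
    """Write an SDF of toy-molecule conformer ensembles with energies.

    Conformers are embedded with distance geometry and given MMFF94
    potential energies (converted to kJ/mol) under the ``E_kJ_mol``
    property; consecutive records of one molecule form one ensemble.
    Returns the number of records written.
    """
    writer = Chem.SDWriter(str(path))
    n_written = 0
    for smiles, expected, desc in TOY_MOLECULES:
        if expected is None:
            continue
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        mol.SetProp("_Name", desc)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31)
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
        mmff = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
        for cid, (_converged, e_kcal) in zip(ids, mmff):
            mol.SetProp("E_kJ_mol", f"{e_kcal * 4.184:.6f}")
            writer.write(mol, confId=int(cid))
            n_written += 1
    writer.close()
    return n_written
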