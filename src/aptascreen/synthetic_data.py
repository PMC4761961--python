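"""Seeded generators for every input class the screening pipeline consumes.

Real inputs to the analysis — docking mode scores, calorimetric isotherms,
curated sequence pools, complex coordinates — either come from engines that
are out of scope here or were never deposited.  These generators emulate the
*statistical structure* each stage assumes, so the whole pipeline is testable
end to end without downloads:

* palindromic and random RNA pools (hairpin-formers vs controls);
* per-engine docking mode scores whose consensus Z_T separates binders from
  non-binders with the reported group contrast (means ~ -4.4 vs ~ -3.6);
* toy protein-RNA complexes with an exact, planted number of hydrogen bonds
  and hydrophobic contacts (and everything else kept far apart);
* one-site binding isotherms via :func:`aptascreen.itc_binding.simulate_isotherm`.

Mode scores are modelled as a floor-clustered location-scale family,
``loc + Gamma(shape, scale)`` with lower = better: docking mode lists pile up
near their best score with a tail of worse poses, which is what makes the
studentized minimum a useful specificity signal.  For binders the single best
mode is additionally pulled ``best_mode_boost`` SDs further down — the
simplest mechanism that produces the reported consensus contrast.  This is an
emulation of score statistics, not a physical docking model.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus_ranking import METHODS, DockingScoreSet
from .sequence_pool import RnaCandidate

__all__ = [
    "BinderModel",
    "gen_palindromic_rna",
    "gen_random_rna",
    "gen_docking_scores",
    "gen_binder_pool_zt",
    "gen_complex_pdb",
]

_BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: bases that pair (WC or wobble) with the key — excluded when planting mismatches
_PAIRS_WITH = {
    "A": {"U"},
    "U": {"A", "G"},
    "G": {"C", "U"},
    "C": {"G"},
}

#: gamma shape of the mode-score family; calibrated by Monte Carlo so that the
#: expected studentized minimum of 10 modes is ~ -1.19 per engine, i.e. a
#: non-binder consensus Z_T of ~ -3.56
DEFAULT_MODE_SHAPE = 1.95
#: binder best-mode pull, in units of the mode-score SD; calibrated so the
#: binder consensus Z_T mean is ~ -4.45
DEFAULT_BINDER_BOOST = 0.39

#: arbitrary per-engine score units (floor location and gamma scale)
DEFAULT_METHOD_PARAMS = {
    "AV": (-9.0, 0.6),  # kcal/mol-like
    "H": (-120.0, 12.0),  # HADDOCK-score-like
    "P": (-60.0, 6.0),  # refined-energy-like
}


@dataclass(frozen=True)
class BinderModel:
    """Score-generating model for one candidate class (binder or nonbinder)."""

    cls: str = "binder"
    method_params: dict = field(default_factory=lambda: dict(DEFAULT_METHOD_PARAMS))
    shape: float = DEFAULT_MODE_SHAPE
    best_mode_boost: float | None = None

    def __post_init__(self) -> None:
        if self.cls not in ("binder", "nonbinder"):
            raise ValueError("cls must be 'binder' or 'nonbinder'")
        for m, (loc, scale) in self.method_params.items():
            if scale <= 0:
                raise ValueError(f"{m}: scale must be positive")
        boost = self.boost
        if boost < 0:
            raise ValueError("best_mode_boost must be >= 0")

    @property
    def boost(self) -> float:
        if self.best_mode_boost is not None:
            return self.best_mode_boost
        return DEFAULT_BINDER_BOOST if self.cls == "binder" else 0.0


def gen_random_rna(length: int, seed: int | np.random.Generator) -> RnaCandidate:
    """Uniform i.i.d. RNA of the given length (deterministic per seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = "".join(rng.choice(_BASES, size=length))
    return RnaCandidate(id=f"random_{length}nt", rna=seq)


def gen_palindromic_rna(
    arm_len: int,
    loop_len: int,
    n_mismatches: int,
    gc_frac: float,
    seed: int | np.random.Generator,
) -> RnaCandidate:
    """Hairpin-forming RNA: reverse-complementary arms around a loop.

    The 5' arm is composed to hit ``gc_frac`` within +/- 1 base; the 3' arm is
    its reverse complement except for exactly ``n_mismatches`` planted
    non-pairing positions.  Mismatches are planted at the outermost arm
    positions so the full-arm register stays the uniquely best one and an
    inverted-repeat detector recovers exactly the planted mismatch count.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    if not 0 <= n_mismatches <= arm_len:
        raise ValueError("need 0 <= n_mismatches <= arm_len")
    if not 0.0 <= gc_frac <= 1.0:
        raise ValueError("gc_frac must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_gc = int(round(gc_frac * arm_len))
    arm = [str(rng.choice(["G", "C"])) for _ in range(n_gc)]
    arm += [str(rng.choice(["A", "U"])) for _ in range(arm_len - n_gc)]
    rng.shuffle(arm)
    arm5 = "".join(arm)
    arm3 = [_COMPLEMENT[b] for b in reversed(arm5)]
    # 3' arm position arm_len-1-k pairs with 5' arm position k; the outermost
    # pairs are k = 0 .. n_mismatches-1
    for k in range(n_mismatches):
        partner = arm5[k]
        choices = [b for b in "ACGU" if b not in _PAIRS_WITH[partner]]
        arm3[arm_len - 1 - k] = str(rng.choice(choices))
    loop = "".join(rng.choice(_BASES, size=loop_len))
    seq = arm5 + loop + "".join(arm3)
    return RnaCandidate(id=f"palindrome_a{arm_len}l{loop_len}m{n_mismatches}", rna=seq)


def gen_docking_scores(
    model: BinderModel,
    n_modes: int = 10,
    seed: int | np.random.Generator | None = 0,
    candidate_id: str = "synthetic",
) -> dict[str, DockingScoreSet]:
    """Per-engine mode-score sets for one candidate, sorted best-first."""
    if n_modes < 2:
        raise ValueError("n_modes must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = {}
    for method in METHODS:
        loc, scale = model.method_params[method]
        theta = scale / np.sqrt(model.shape)  # so the mode-score SD equals `scale`
        x = loc + rng.gamma(model.shape, theta, size=n_modes)
        if model.boost > 0:
            x[np.argmin(x)] -= model.boost * scale
        x.sort()
        out[method] = DockingScoreSet(
            candidate_id=candidate_id,
            method=method,
            mode_scores=tuple(float(v) for v in x),
        )
    return out


def gen_binder_pool_zt(
    n_binders: int = 18,
    n_nonbinders: int = 5,
    n_modes: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus Z_T samples for a pool of binders and nonbinder controls."""
    from .consensus_ranking import method_zscore, total_zscore

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    binder = BinderModel(cls="binder")
    nonbinder = BinderModel(cls="nonbinder")

    def zt(model: BinderModel) -> float:
        sets = gen_docking_scores(model, n_modes=n_modes, seed=rng)
        z = {m: method_zscore(sets[m]) for m in METHODS}
        return total_zscore(z["AV"], z["H"], z["P"])

    return (
        np.array([zt(binder) for _ in range(n_binders)]),
        np.array([zt(nonbinder) for _ in range(n_nonbinders)]),
    )


# ---------------------------------------------------------------------------
# toy complexes


def _pdb_line(
    serial: int, name: str, resname: str, chain: str, resnum: int, xyz, element: str
) -> str:
    # PDB fixed columns; atom names of <4 chars start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def gen_complex_pdb(
    k_hbonds: int,
    k_hydrophobic: int,
    seed: int | np.random.Generator | None = 0,
    max_pairs: int = 64,
) -> str:
    """Minimal protein+RNA PDB text with exactly the planted contact counts.

    Each planted hydrogen bond is a lysine NZ donor 3.0 A from an adenosine
    OP1 acceptor; each hydrophobic contact is a leucine CD1 3.5 A from an
    adenosine C5'.  Planted sites sit >= 12 A apart and every non-planted
    intermolecular atom pair is > 5 A, so detection at default cutoffs
    recovers the counts exactly.  The whole complex is given a seeded random
    rigid rotation and translation (counts are distance-based, hence
    invariant).
    """
    if k_hbonds < 0 or k_hydrophobic < 0:
        raise ValueError("contact counts must be >= 0")
    if k_hbonds + k_hydrophobic > max_pairs:
        raise ValueError(f"cannot place more than {max_pairs} planted pairs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    protein_atoms = []  # (name, resname, resnum, xyz, element)
    rna_atoms = []
    site = 0
    for _ in range(k_hbonds):
        x = 12.0 * site
        resnum = site + 1
        protein_atoms.append(("CA", "LYS", resnum, (x, -8.0, 0.0), "C"))
        protein_atoms.append(("NZ", "LYS", resnum, (x, 0.0, 0.0), "N"))
        rna_atoms.append(("OP1", "A", resnum, (x, 3.0, 0.0), "O"))
        rna_atoms.append(("P", "A", resnum, (x, 11.0, 0.0), "P"))
        site += 1
    for _ in range(k_hydrophobic):
        x = 12.0 * site
        resnum = site + 1
        protein_atoms.append(("CA", "LEU", resnum, (x, -8.0, 0.0), "C"))
        protein_atoms.append(("CD1", "LEU", resnum, (x, 0.0, 0.0), "C"))
        rna_atoms.append(("C5'", "A", resnum, (x, 3.5, 0.0), "C"))
        rna_atoms.append(("P", "A", resnum, (x, 11.5, 0.0), "P"))
        site += 1
    if not protein_atoms:  # keep both chains non-empty even for (0, 0)
        protein_atoms.append(("CA", "GLY", 1, (0.0, -50.0, 0.0), "C"))
    if not rna_atoms:
        rna_atoms.append(("P", "A", 1, (0.0, 50.0, 0.0), "P"))

    # seeded rigid motion
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)

    def place(xyz):
        return rot @ np.asarray(xyz) + shift

    lines = []
    serial = 1
    for name, resname, resnum, xyz, element in protein_atoms:
        lines.append(_pdb_line(serial, name, resname, "A", resnum, place(xyz), element))
        serial += 1
    lines.append("TER\n")
    for name, resname, resnum, xyz, element in rna_atoms:
        lines.append(_pdb_line(serial, name, resname, "B", resnum, place(xyz), element))
        serial += 1
    lines.append("END\n")
    return "".join(lines)
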