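"""Structure file I/O and synthetic chain generation.

Reads mmCIF/PDB files into :class:`ProteinChain` objects (an identifier, a
one-letter sequence and the ordered C-alpha trace in angstroms), writes
chains back to PDB, and generates synthetic chains — helices, strands and
self-avoiding coils — plus whole labelled benchmark databases so the full
search pipeline can be exercised without any external structure archive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_CHAIN_LENGTH = 3


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read or parsed."""


@dataclass(frozen=True)
class ProteinChain:
    """A single polymer chain reduced to its C-alpha trace.

    Parameters
    ----------
    id : str
        Identifier, canonically a UniProt-style accession.
    sequence : str
        One-letter amino-acid sequence; unknown residues are ``X``.
    ca_coords : numpy.ndarray
        ``(n, 3)`` float array of C-alpha positions in angstrom, ordered
        by residue number.
    """

    id: str
    sequence: str
    ca_coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        object.__setattr__(self, "ca_coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (n, 3) array")
        if len(self.sequence) != coords.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"{coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < MIN_CHAIN_LENGTH:
            raise ValueError(f"chain needs >= {MIN_CHAIN_LENGTH} residues")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinate in chain")

    def __len__(self) -> int:
        return self.ca_coords.shape[0]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(float(np.linalg.det(rot)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation determinant must be +1 (no reflection)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator) -> "RigidTransform":
        """Uniform random rotation (QR of a Gaussian matrix) plus a
        translation drawn from N(0, 50 A) per axis."""
        mat = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(mat)
        q = q * np.sign(np.diag(r))  # make decomposition unique
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        return RigidTransform(q, rng.normal(scale=50.0, size=3))


# ---------------------------------------------------------------------------
# File I/O


_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def parse_structure(path: str | Path, format: str = "auto") -> list[ProteinChain]:
    """Read a PDB or mmCIF file and return one ProteinChain per polymer chain.

    Residues are ordered by residue number (insertion codes break ties
    lexicographically); residues lacking a C-alpha atom are skipped and
    counted in a warning. Chains with fewer than three usable C-alpha atoms
    are dropped with a warning. Only the first model of multi-model files is
    used.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no coordinate model")

    chains: list[ProteinChain] = []
    for chain in st[0]:
        residues = sorted(chain, key=lambda r: (r.seqid.num, r.seqid.icode))
        coords, letters, missing_ca = [], [], 0
        for res in residues:
            if res.het_flag == "H" and gemmi.find_tabulated_residue(res.name) is not None \
                    and not gemmi.find_tabulated_residue(res.name).is_amino_acid():
                continue  # heteroatom ligands/waters are not part of the trace
            ca = res.find_atom("CA", "*")
            if ca is None:
                missing_ca += 1
                continue
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            letters.append(_one_letter(res.name))
        if missing_ca:
            logger.warning(
                "%s chain %s: %d residue(s) without a C-alpha atom skipped",
                path.name, chain.name, missing_ca,
            )
        if len(coords) < MIN_CHAIN_LENGTH:
            logger.warning(
                "%s chain %s: only %d usable C-alpha atoms (< %d), chain skipped",
                path.name, chain.name, len(coords), MIN_CHAIN_LENGTH,
            )
            continue
        chains.append(
            ProteinChain(chain.name, "".join(letters), np.asarray(coords))
        )
    return chains


_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_chain(chain: ProteinChain, path: str | Path, format: str = "pdb") -> None:
    """Write a chain as a PDB file of C-alpha ATOM records.

    The PDB chain-id field is a single character; longer ids are truncated
    to their first character (logged) while the full id is kept in the
    TITLE record.
    """
    if format != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    chain_id = chain.id[:1] if chain.id else "A"
    if len(chain.id) > 1:
        logger.warning("chain id %r truncated to %r for PDB output", chain.id, chain_id)
    st = gemmi.Structure()
    st.name = chain.id
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain_id)
    for i, (letter, xyz) in enumerate(zip(chain.sequence, chain.ca_coords), start=1):
        res = gemmi.Residue()
        res.name = _THREE_LETTER.get(letter, "UNK")
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        gchain.add_residue(res)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Synthetic chain generators

HELIX_RADIUS = 2.3        # A
HELIX_TWIST = math.radians(100.0)
HELIX_RISE = 1.5          # A per residue
STRAND_RISE = 3.5         # A per residue along the strand axis
STRAND_OFFSET = 0.9       # alternating lateral zigzag, A
COIL_STEP = 3.8           # virtual C-alpha bond length, A
COIL_CLASH_DIST = 3.0     # self-avoidance cutoff, A


def _require_length(n: int) -> None:
    if n < MIN_CHAIN_LENGTH:
        raise ValueError(f"need n >= {MIN_CHAIN_LENGTH}, got {n}")


def make_helix(n: int, id: str = "HELIX") -> ProteinChain:
    """Ideal poly-alanine alpha-helix: radius 2.3 A, 100 deg twist per
    residue, 1.5 A rise — the canonical C-alpha helix geometry."""
    _require_length(n)
    i = np.arange(n)
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(i * HELIX_TWIST),
        HELIX_RADIUS * np.sin(i * HELIX_TWIST),
        i * HELIX_RISE,
    ])
    return ProteinChain(id, "A" * n, coords)


def make_strand(n: int, id: str = "STRAND") -> ProteinChain:
    """Extended poly-glycine strand: 3.5 A rise with an alternating
    +-0.9 A lateral zigzag. A fixed, deterministic extended geometry."""
    _require_length(n)
    i = np.arange(n)
    coords = np.column_stack([
        i * STRAND_RISE,
        np.where(i % 2 == 0, STRAND_OFFSET, -STRAND_OFFSET),
        np.zeros(n),
    ])
    return ProteinChain(id, "G" * n, coords)


def make_coil(n: int, seed: int, id: str = "COIL") -> ProteinChain:
    """Self-avoiding random walk with fixed 3.8 A steps.

    Models unstructured/disordered regions. Candidate directions are drawn
    uniformly on the sphere; a step is rejected if it lands within 3.0 A of
    any earlier residue. If 200 rejections accumulate at one step, the
    candidate with the largest clearance is accepted so generation always
    terminates (vanishingly rare for chains of a few thousand residues).
    Deterministic for a given ``(n, seed)``.
    """
    _require_length(n)
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        best, best_clearance = None, -np.inf
        for _ in range(200):
            vec = rng.normal(size=3)
            vec *= COIL_STEP / np.linalg.norm(vec)
            cand = coords[i - 1] + vec
            clearance = np.min(np.linalg.norm(coords[: max(i - 1, 1)] - cand, axis=1))
            if clearance >= COIL_CLASH_DIST:
                best = cand
                break
            if clearance > best_clearance:
                best, best_clearance = cand, clearance
        coords[i] = best
    return ProteinChain(id, "G" * n, coords)


def apply_rigid_transform(chain: ProteinChain, t: RigidTransform) -> ProteinChain:
    """Return the chain with ``rotation @ x + translation`` applied to every
    C-alpha; sequence and id are preserved."""
    coords = chain.ca_coords @ t.rotation.T + t.translation
    return ProteinChain(chain.id, chain.sequence, coords)


def perturb_coordinates(chain: ProteinChain, sigma: float, seed: int) -> ProteinChain:
    """Add independent zero-mean Gaussian noise (std ``sigma`` A) to every
    coordinate component. ``sigma=0`` returns an identical copy."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=chain.ca_coords.shape) if sigma > 0 else 0.0
    return ProteinChain(chain.id, chain.sequence, chain.ca_coords + noise)


def generate_benchmark_db(
    n_families: int,
    members_per_family: int,
    length_range: tuple[int, int] = (50, 200),
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[list[ProteinChain], pd.DataFrame]:
    """Generate a labelled database of synthetic structural families.

    Each family starts from one seed chain (helix, strand or coil, chosen at
    random, with a random length in ``length_range``). Because the helix and
    strand generators are deterministic, every seed chain additionally gets
    its own fixed coordinate jitter (Gaussian, std 5 A) so that two families
    of the same secondary-structure class are still distinct folds. Every
    member is then a coordinate-perturbed (Gaussian, std ``sigma``) and
    rigidly transformed copy of its family seed. Ids are accession-shaped
    (``P<5 digits>``) so they can flow through identifier resolution
    unchanged.

    Returns the chains and a label table with columns ``id`` and ``family``
    suitable for recall evaluation.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("counts must be >= 1")
    lo, hi = length_range
    if not (MIN_CHAIN_LENGTH <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    makers = [make_helix, make_strand, lambda n, id: make_coil(n, int(rng.integers(2**31)), id)]
    chains: list[ProteinChain] = []
    rows = []
    counter = 0
    for fam in range(n_families):
        length = int(rng.integers(lo, hi + 1))
        seed_chain = makers[int(rng.integers(3))](length, id=f"F{fam}")
        # family-identity jitter: separates same-class families into
        # distinct folds while keeping members tightly clustered
        seed_chain = perturb_coordinates(seed_chain, 5.0, int(rng.integers(2**31)))
        for _ in range(members_per_family):
            member_id = f"P{counter:05d}"
            counter += 1
            perturbed = perturb_coordinates(seed_chain, sigma, int(rng.integers(2**31)))
            placed = apply_rigid_transform(perturbed, RigidTransform.random(rng))
            chains.append(ProteinChain(member_id, placed.sequence, placed.ca_coords))
            rows.append({"id": member_id, "family": fam})
    return chains, pd.DataFrame(rows)


def write_family_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write the family-label table as CSV with columns id,family."""
    labels.to_csv(path, index=False, columns=["id", "family"])
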