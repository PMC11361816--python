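"""Interface residue detection, sequence mapping and disorder scoring.

A residue is part of a two-chain interface when any of its heavy atoms lies
within a distance cutoff (10 Angstrom by default, the convention used for
assessing predicted complex models) of any heavy atom of the partner chain.
Interface residues detected in structure numbering are shifted to 1-based
protein sequence coordinates through a SIFTS-style residue-level mapping,
after which per-residue intrinsic-disorder propensities (IUPred-style
scores in [0, 1]) summarize how disordered an interface is: the fraction of
interface residues scoring strictly above 0.4.  Interfaces of bona fide
domain-domain contacts are expected to be largely ordered; a high disorder
fraction is a red flag that a Pfam match does not cover a folded domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .errors import CoverageError, FlatParseError

__all__ = [
    "Residue",
    "ToyStructure",
    "ResidueMapping",
    "DisorderProfile",
    "load_structure",
    "interface_residues",
    "map_to_sequence",
    "interface_disorder_fraction",
    "load_disorder_profiles",
]

DEFAULT_CONTACT_CUTOFF = 10.0  # Angstrom
DEFAULT_DISORDER_THRESHOLD = 0.4


@dataclass(frozen=True)
class Residue:
    """One residue: an opaque author-numbering id and heavy-atom coordinates."""

    res_id: str
    coords: np.ndarray  # (n_atoms, 3) float array, Angstrom

    def __post_init__(self):
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
            raise ValueError("residue needs an (n_atoms, 3) coordinate array")
        object.__setattr__(self, "coords", arr)


@dataclass
class ToyStructure:
    """A minimal in-memory structure: ordered residues per chain."""

    chains: dict[str, list[Residue]]
    name: str = ""

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not present in structure {self.name!r}")
        return self.chains[chain_id]


def load_structure(path: str | Path, model_index: int = 0) -> ToyStructure:
    """Read a PDB or mmCIF file into a :class:`ToyStructure`.

    Heavy atoms only; for alternate locations the highest-occupancy
    conformer is kept so geometry is single-conformer deterministic.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    structure = parser.get_structure(path.stem, str(path))
    model = list(structure)[model_index]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            het, resseq, icode = res.id
            # pick the best altloc per atom name, skip hydrogens
            best: dict[str, tuple[float, np.ndarray]] = {}
            for atom in res.get_unpacked_list():
                if atom.element == "H":
                    continue
                occ = atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                name = atom.get_name()
                if name not in best or occ > best[name][0]:
                    best[name] = (occ, atom.coord.astype(float))
            if not best:
                continue
            res_id = f"{resseq}{icode.strip()}"
            coords = np.vstack([c for _, c in best.values()])
            residues.append(Residue(res_id=res_id, coords=coords))
        if residues:
            chains[chain.id] = residues
    return ToyStructure(chains=chains, name=path.stem)


def _flatten(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Stack residue atoms into one array with a parallel residue-index array."""
    coords = np.vstack([r.coords for r in residues])
    owner = np.concatenate(
        [np.full(len(r.coords), i, dtype=int) for i, r in enumerate(residues)]
    )
    return coords, owner


def interface_residues(
    s: ToyStructure,
    chain_x: str,
    chain_y: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> tuple[set[str], set[str]]:
    """Residue ids on each chain with any heavy atom within ``cutoff`` of the other chain."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_x = s.chain(chain_x)
    res_y = s.chain(chain_y)
    if not res_x or not res_y:
        return set(), set()
    cx, ox = _flatten(res_x)
    cy, oy = _flatten(res_y)
    tree_y = cKDTree(cy)
    pairs = tree_y.query_ball_point(cx, r=cutoff)
    hit_x: set[str] = set()
    hit_y: set[str] = set()
    for i, neigh in enumerate(pairs):
        if neigh:
            hit_x.add(res_x[ox[i]].res_id)
            for j in neigh:
                hit_y.add(res_y[oy[j]].res_id)
    return hit_x, hit_y


class ResidueMapping:
    """(pdb, chain, structure residue id) -> (protein accession, 1-based index)."""

    def __init__(
        self,
        entries: Mapping[tuple[str, str, str], tuple[str, int]] | None = None,
    ):
        self._entries = dict(entries or {})

    def __len__(self):
        return len(self._entries)

    def get(self, pdb_id: str, chain: str, res_id: str) -> tuple[str, int] | None:
        return self._entries.get((pdb_id, chain, res_id))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMapping":
        """Columns: pdb, chain, pdb_res, accession, seq_index (header tolerated)."""
        entries: dict[tuple[str, str, str], tuple[str, int]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() == "pdb":
                    continue
                if len(parts) < 5:
                    raise FlatParseError(f"mapping row needs 5 columns: {line!r}")
                entries[(parts[0], parts[1], parts[2])] = (parts[3], int(parts[4]))
        return cls(entries)


def map_to_sequence(
    residues: Iterable[str],
    mapping: ResidueMapping,
    pdb_id: str,
    chain: str,
) -> tuple[set[tuple[str, int]], list[str]]:
    """Translate structure residue ids to (accession, sequence index).

    Residues absent from the mapping are returned in the ``unmapped`` list,
    never silently dropped.
    """
    mapped: set[tuple[str, int]] = set()
    unmapped: list[str] = []
    for res_id in residues:
        hit = mapping.get(pdb_id, chain, res_id)
        if hit is None:
            unmapped.append(res_id)
        else:
            mapped.add(hit)
    return mapped, unmapped


@dataclass
class DisorderProfile:
    """Per-residue disorder propensity over a full protein sequence, 1-based."""

    accession: str
    scores: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 1:
            raise ValueError("scores must be a 1-D array")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("disorder scores must lie in [0, 1]")
        self.scores = arr

    def __len__(self):
        return len(self.scores)

    def score_at(self, seq_index: int) -> float:
        """Score at a 1-based sequence position."""
        if not 1 <= seq_index <= len(self.scores):
            raise CoverageError(
                f"position {seq_index} outside disorder profile of "
                f"{self.accession} (length {len(self.scores)})"
            )
        return float(self.scores[seq_index - 1])


def load_disorder_profiles(path: str | Path) -> dict[str, DisorderProfile]:
    """Read profiles from a TSV with columns accession, position, score."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["accession", "position", "score"], header=None,
    )
    if len(df) and df.iloc[0]["accession"] == "accession":
        df = df.iloc[1:]
    df["position"] = df["position"].astype(int)
    df["score"] = df["score"].astype(float)
    profiles = {}
    for acc, grp in df.groupby("accession", sort=False):
        length = int(grp["position"].max())
        scores = np.zeros(length)
        scores[grp["position"].to_numpy() - 1] = grp["score"].to_numpy()
        profiles[acc] = DisorderProfile(accession=acc, scores=scores)
    return profiles


def interface_disorder_fraction(
    iface_residues_by_chain: Mapping[str, Iterable[tuple[str, int]]],
    profiles: Mapping[str, DisorderProfile],
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> tuple[dict[str, float | None], float | None]:
    """Fraction of interface residues with disorder score strictly above ``threshold``.

    ``iface_residues_by_chain`` maps a chain id to its interface residues in
    sequence coordinates, each an (accession, 1-based index) pair.  Returns
    per-chain fractions and the whole-interface fraction pooling both
    chains.  An empty residue set yields ``None`` with a warning rather than
    zero — zero would masquerade as "fully ordered".
    """
    per_chain: dict[str, float | None] = {}
    pooled_hits = 0
    pooled_total = 0
    for chain, residues in iface_residues_by_chain.items():
        residues = list(residues)
        if not residues:
            warnings.warn(
                f"chain {chain!r} has no interface residues; "
                "disorder fraction undefined",
                stacklevel=2,
            )
            per_chain[chain] = None
            continue
        hits = 0
        for acc, idx in residues:
            if acc not in profiles:
                raise CoverageError(f"no disorder profile for accession {acc}")
            if profiles[acc].score_at(idx) > threshold:
                hits += 1
        per_chain[chain] = hits / len(residues)
        pooled_hits += hits
        pooled_total += len(residues)
    if pooled_total == 0:
        warnings.warn("interface is empty; disorder fraction undefined", stacklevel=2)
        return per_chain, None
    return per_chain, pooled_hits / pooled_total
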