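"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to the pipeline — a 3did flat file, the curated benchmark
feature table, PPI networks with Pfam matches, pLDDT and disorder profiles,
interface structures — all come from external resources.  The generators
here emulate each input class with a planted truth so every stage can be
validated end to end: classification against intended composition classes,
logistic fitting against planted coefficients, network enrichment against
planted domain-pair wiring, boundary refinement against known order/
disorder plateaus, and interface detection against constructed geometry.

Every generator is a pure function of its config; the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ddi_scan import DomainMatch, PLDDTProfile
from .errors import GenerationError
from .feature_table import FEATURE_COLUMNS
from .interface_geometry import DisorderProfile, Residue, ToyStructure
from .threedid_io import ChainMap, DDIClass, canonical_pair

__all__ = [
    "FlatConfig",
    "BenchmarkConfig",
    "NetworkConfig",
    "ProfileConfig",
    "StructureConfig",
    "gen_3did_flat",
    "gen_benchmark_table",
    "gen_ppi_network",
    "gen_plddt_disorder_profiles",
    "gen_toy_structure",
    "structure_to_pdb",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# 3did flat files


@dataclass(frozen=True)
class FlatConfig:
    """Composition of a synthetic 3did flat file."""

    seed: int = 0
    n_intrachain: int = 10
    n_homoprotein: int = 20
    n_hetero: int = 15
    max_structures: int = 3
    max_contacts: int = 20


def _contacts(rng, lo=5, hi=20) -> list[tuple[str, str]]:
    n = int(rng.integers(lo, hi + 1))
    res_a = rng.integers(1, 300, size=n)
    res_b = rng.integers(1, 300, size=n)
    return [(str(a), str(b)) for a, b in zip(res_a, res_b)]


def gen_3did_flat(
    cfg: FlatConfig = FlatConfig(),
) -> tuple[str, pd.DataFrame, ChainMap]:
    """Emit a flat file with known intrachain/homo/hetero composition.

    Returns the flat-file text, a truth table (pfam_a, pfam_b, class) and
    the chain map resolving every interchain chain to a protein accession.
    """
    for n in (cfg.n_intrachain, cfg.n_homoprotein, cfg.n_hetero):
        if n < 0:
            raise GenerationError("type counts must be non-negative")
    rng = np.random.default_rng(cfg.seed)
    classes = (
        [DDIClass.INTRACHAIN_ONLY] * cfg.n_intrachain
        + [DDIClass.HOMOPROTEIN_ONLY] * cfg.n_homoprotein
        + [DDIClass.HETERO_INTERCHAIN] * cfg.n_hetero
    )
    rng.shuffle(classes)

    lines: list[str] = []
    truth_rows = []
    cmap_entries: dict[tuple[str, str], str] = {}
    pdb_counter = 0
    for i, cls in enumerate(classes):
        pfam_a, pfam_b = canonical_pair(f"PF9{2 * i:04d}", f"PF9{2 * i + 1:04d}")
        lines.append(
            f"#=ID\tdomA{i}\tdomB{i}\t({pfam_a}.1@Pfam\t{pfam_b}.2@Pfam)"
        )
        n_structures = int(rng.integers(1, cfg.max_structures + 1))
        for s in range(n_structures):
            pdb_counter += 1
            pdb = f"s{pdb_counter:04d}"
            score = float(np.round(rng.uniform(1, 15), 3))
            zscore = float(np.round(rng.uniform(0, 10), 3))
            if cls is DDIClass.INTRACHAIN_ONLY:
                chain_a = chain_b = "A"
            else:
                chain_a, chain_b = "A", "B"
                if cls is DDIClass.HOMOPROTEIN_ONLY:
                    acc = f"HP{i:04d}"
                    cmap_entries[(pdb, "A")] = acc
                    cmap_entries[(pdb, "B")] = acc
                else:
                    # hetero: every structure heterodimeric keeps truth exact
                    cmap_entries[(pdb, "A")] = f"XP{i:04d}a"
                    cmap_entries[(pdb, "B")] = f"XP{i:04d}b"
            lines.append(
                f"#=3D\t{pdb}\t{chain_a}:1-100\t{chain_b}:1-100\t{score}\t{zscore}"
            )
            for res_a, res_b in _contacts(rng, hi=cfg.max_contacts):
                lines.append(f"{res_a}\t{res_b}")
            # interchain-classed types may additionally carry an intrachain
            # interface in the same structure; it must not flip the class
            if cls is not DDIClass.INTRACHAIN_ONLY and rng.random() < 0.3:
                lines.append(
                    f"#=3D\t{pdb}\tA:1-100\tA:120-220\t"
                    f"{np.round(rng.uniform(1, 15), 3)}\t"
                    f"{np.round(rng.uniform(0, 10), 3)}"
                )
                for res_a, res_b in _contacts(rng, hi=cfg.max_contacts):
                    lines.append(f"{res_a}\t{res_b}")
        lines.append("//")
        truth_rows.append(
            {"pfam_a": pfam_a, "pfam_b": pfam_b, "class": cls.value}
        )
    truth = pd.DataFrame(truth_rows, columns=["pfam_a", "pfam_b", "class"])
    return "\n".join(lines) + ("\n" if lines else ""), truth, ChainMap(cmap_entries)


# ---------------------------------------------------------------------------
# benchmark feature table


@dataclass(frozen=True)
class BenchmarkConfig:
    """A labeled feature table drawn from a planted logistic model.

    Defaults mirror the curated benchmark's composition: 80 rows, of which
    5 involve an engineered-scaffold family (Ankyrin PF00023 / V-set
    PF07686), with approval driven by the interface-evidence features.
    Covariates are shaped like the real annotations: right-skewed positive
    z-scores, [0, 1]-bounded DockQ and interface disorder.
    """

    seed: int = 0
    n_rows: int = 80
    intercept: float = -3.0
    coefficients: tuple[tuple[str, float], ...] = (
        ("zscore_3did", 0.7),
        ("af_dockq", 2.5),
        ("iupred_interface", -2.5),
    )
    n_engineered: int = 5
    noise_columns: tuple[str, ...] = ()
    missing_dockq_fraction: float = 0.0


def gen_benchmark_table(
    cfg: BenchmarkConfig = BenchmarkConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Labeled feature rows with Bernoulli labels from the planted model."""
    if cfg.n_rows < 10:
        raise GenerationError("benchmark table needs at least 10 rows")
    if cfg.n_engineered > cfg.n_rows:
        raise GenerationError("more engineered rows requested than rows")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rows
    z = np.round(rng.gamma(shape=2.0, scale=1.5, size=n) + 0.5, 4)
    score = np.round(z * 3.0 + rng.normal(0, 1.0, size=n), 4)
    dockq = np.round(rng.beta(2.0, 2.0, size=n), 4)
    iupred = np.round(rng.beta(2.0, 5.0, size=n), 4)
    n_contacts = 5 + rng.poisson(3.0 * z)
    n_inter = 1 + rng.poisson(2.0, size=n)
    n_intra = rng.poisson(1.0, size=n)

    covariates = {
        "zscore_3did": z,
        "score_3did": score,
        "af_dockq": dockq,
        "iupred_interface": iupred,
        "n_contacts": n_contacts.astype(float),
        "n_interchain_structures": n_inter.astype(float),
        "n_intrachain_structures": n_intra.astype(float),
    }
    eta = np.full(n, cfg.intercept)
    for name, beta in cfg.coefficients:
        if name not in covariates:
            raise GenerationError(f"unknown planted covariate {name!r}")
        eta = eta + beta * covariates[name]
    prob = 1.0 / (1.0 + np.exp(-eta))
    approved = rng.random(n) < prob

    pairs = []
    engineered_idx = set(range(cfg.n_engineered))
    engineered_pool = ["PF00023", "PF07686"]
    for i in range(n):
        if i in engineered_idx:
            pairs.append(canonical_pair(engineered_pool[i % 2], f"PF8{i:04d}"))
        else:
            pairs.append(canonical_pair(f"PF8{2 * i:04d}", f"PF8{2 * i + 1:04d}"))

    table = pd.DataFrame(
        {
            "pfam_a": [p[0] for p in pairs],
            "pfam_b": [p[1] for p in pairs],
            "zscore_3did": z,
            "score_3did": score,
            "n_contacts": n_contacts,
            "n_interchain_structures": n_inter,
            "n_intrachain_structures": n_intra,
            "af_dockq": dockq,
            "iupred_interface": iupred,
            "label": np.where(approved, "approved", "nonapproved"),
        },
        columns=FEATURE_COLUMNS,
    )
    for name in cfg.noise_columns:
        table[name] = np.round(rng.normal(0, 1, size=n), 4)
    if cfg.missing_dockq_fraction > 0:
        drop = rng.random(n) < cfg.missing_dockq_fraction
        table.loc[drop, "af_dockq"] = np.nan
    truth = {
        "intercept": cfg.intercept,
        "coefficients": dict(cfg.coefficients),
        "probabilities": prob,
        "engineered_rows": sorted(engineered_idx),
    }
    return table, truth


# ---------------------------------------------------------------------------
# PPI network with planted domain-pair enrichment


@dataclass(frozen=True)
class NetworkConfig:
    """A PPI network whose edges may be planted with complementary domains.

    ``planted_fraction`` of edges receive a complementary high-confidence
    Pfam pair (one side each); every protein independently also carries
    background matches at ``background_match_rate`` per HC accession pool
    draw, so chance pairings exist like in a real interactome scan.
    """

    seed: int = 0
    n_proteins: int = 200
    n_edges: int = 400
    degree_sequence: tuple[int, ...] | None = None
    planted_fraction: float = 0.5
    background_match_rate: float = 0.05
    n_hc_types: int = 10
    protein_length: int = 300


def gen_ppi_network(
    cfg: NetworkConfig = NetworkConfig(),
) -> tuple[nx.Graph, list[DomainMatch], set[tuple[str, str]], dict]:
    """Network + domain matches + HC type set + truth.

    Truth records the planted edges and the sequences dictionary used for
    fragment export.
    """
    if cfg.n_proteins < 2:
        raise GenerationError("need at least two proteins")
    rng = np.random.default_rng(cfg.seed)
    names = [f"PROT{i:04d}" for i in range(cfg.n_proteins)]
    if cfg.degree_sequence is not None:
        if len(cfg.degree_sequence) != cfg.n_proteins:
            raise GenerationError("degree sequence length must equal n_proteins")
        g0 = nx.havel_hakimi_graph(list(cfg.degree_sequence))
        g = nx.relabel_nodes(g0, {i: names[i] for i in g0.nodes()})
    else:
        g0 = nx.gnm_random_graph(
            cfg.n_proteins, cfg.n_edges, seed=int(rng.integers(0, 2**31 - 1))
        )
        g = nx.relabel_nodes(g0, {i: names[i] for i in g0.nodes()})

    hc_accs = [f"PF7{i:04d}" for i in range(2 * cfg.n_hc_types)]
    hc_types = {
        canonical_pair(hc_accs[2 * i], hc_accs[2 * i + 1])
        for i in range(cfg.n_hc_types)
    }

    matches: list[DomainMatch] = []

    def random_match(protein: str, pfam: str) -> DomainMatch:
        start = int(rng.integers(20, cfg.protein_length - 120))
        length = int(rng.integers(60, 100))
        return DomainMatch(
            protein=protein,
            pfam=pfam,
            start=start,
            end=min(start + length, cfg.protein_length),
            evalue=float(10.0 ** -rng.uniform(3, 30)),
            score=float(np.round(rng.uniform(20, 200), 1)),
        )

    # background matches
    for name in names:
        for acc in hc_accs:
            if rng.random() < cfg.background_match_rate:
                matches.append(random_match(name, acc))

    # planted complementary pairs on a fraction of edges
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    planted_edges = []
    hc_list = sorted(hc_types)
    for a, b in edges:
        if a != b and rng.random() < cfg.planted_fraction:
            x, y = hc_list[int(rng.integers(0, len(hc_list)))]
            matches.append(random_match(a, x))
            matches.append(random_match(b, y))
            planted_edges.append((a, b))

    sequences = {
        name: "".join(rng.choice(_AA, size=cfg.protein_length)) for name in names
    }
    truth = {"planted_edges": planted_edges, "sequences": sequences}
    return g, matches, hc_types, truth


# ---------------------------------------------------------------------------
# pLDDT and disorder profiles


@dataclass(frozen=True)
class ProfileConfig:
    """pLDDT plateaus over true domain intervals, disorder anti-correlated."""

    seed: int = 0
    n_proteins: int = 20
    length: int = 300
    plateau: float = 95.0
    baseline: float = 40.0
    noise_sd: float = 0.0
    min_domain_length: int = 60
    max_domain_length: int = 120


def gen_plddt_disorder_profiles(
    cfg: ProfileConfig = ProfileConfig(),
) -> tuple[dict[str, PLDDTProfile], dict[str, DisorderProfile], pd.DataFrame]:
    """One true ordered interval per protein; truth records its endpoints."""
    if cfg.length < cfg.max_domain_length + 20:
        raise GenerationError("protein length too short for the domain range")
    rng = np.random.default_rng(cfg.seed)
    plddt: dict[str, PLDDTProfile] = {}
    disorder: dict[str, DisorderProfile] = {}
    truth_rows = []
    for i in range(cfg.n_proteins):
        acc = f"Q{i:05d}"
        dom_len = int(rng.integers(cfg.min_domain_length, cfg.max_domain_length + 1))
        start = int(rng.integers(11, cfg.length - dom_len - 10))
        end = start + dom_len - 1
        values = np.full(cfg.length, cfg.baseline)
        values[start - 1 : end] = cfg.plateau
        if cfg.noise_sd > 0:
            values = values + rng.normal(0, cfg.noise_sd, size=cfg.length)
        values = np.clip(values, 0.0, 100.0)
        dis = np.clip((100.0 - values) / 100.0 - 0.05, 0.0, 1.0)
        plddt[acc] = PLDDTProfile(accession=acc, values=values)
        disorder[acc] = DisorderProfile(accession=acc, scores=dis)
        truth_rows.append({"accession": acc, "start": start, "end": end})
    truth = pd.DataFrame(truth_rows, columns=["accession", "start", "end"])
    return plddt, disorder, truth


# ---------------------------------------------------------------------------
# toy two-chain structures


@dataclass(frozen=True)
class StructureConfig:
    """Two chains with a planted set of residue contacts.

    Chain A residues sit on a line, ``spacing`` Angstrom apart; chain B
    residues sit on a parallel line ``far_distance`` away except for the
    planted contact residues, which are moved to ``contact_distance`` of
    their chain-A partner.  With default geometry every planted pair is
    well inside a 10 Angstrom cutoff and every other pair is well outside.
    """

    seed: int = 0
    n_residues: int = 30
    n_contacts: int = 5
    contact_distance: float = 6.0
    far_distance: float = 50.0
    spacing: float = 20.0
    atoms_per_residue: int = 1
    jitter: float = 0.8


def gen_toy_structure(
    cfg: StructureConfig = StructureConfig(),
) -> tuple[ToyStructure, tuple[set[str], set[str]]]:
    """Construct the structure and the intended interface residue sets."""
    if cfg.n_residues < 1:
        raise GenerationError("need at least one residue per chain")
    if cfg.n_contacts > cfg.n_residues:
        raise GenerationError("more planted contacts than residues")
    jr = cfg.jitter if cfg.atoms_per_residue > 1 else 0.0
    if cfg.contact_distance + 2 * jr >= 10.0:
        raise GenerationError("planted contacts would not sit inside a 10 A cutoff")
    off_axis = np.hypot(cfg.spacing, cfg.contact_distance)
    if min(cfg.far_distance, off_axis) - 2 * jr <= 12.0:
        raise GenerationError("non-contact residues would crowd the cutoff")
    rng = np.random.default_rng(cfg.seed)

    idx_a = rng.choice(cfg.n_residues, size=cfg.n_contacts, replace=False)
    idx_b = rng.choice(cfg.n_residues, size=cfg.n_contacts, replace=False)
    partner = dict(zip(idx_b, idx_a))

    def atoms(center: np.ndarray) -> np.ndarray:
        if cfg.atoms_per_residue == 1:
            return center[None, :]
        offsets = rng.uniform(-1, 1, size=(cfg.atoms_per_residue - 1, 3))
        norms = np.linalg.norm(offsets, axis=1, keepdims=True)
        offsets = offsets / np.maximum(norms, 1e-9) * rng.uniform(
            0, cfg.jitter, size=(cfg.atoms_per_residue - 1, 1)
        )
        return np.vstack([center[None, :], center[None, :] + offsets])

    chain_a = [
        Residue(res_id=str(i + 1), coords=atoms(np.array([cfg.spacing * i, 0.0, 0.0])))
        for i in range(cfg.n_residues)
    ]
    chain_b = []
    for j in range(cfg.n_residues):
        if j in partner:
            i = partner[j]
            center = np.array([cfg.spacing * i, cfg.contact_distance, 0.0])
        else:
            center = np.array([cfg.spacing * j, cfg.far_distance, 0.0])
        chain_b.append(Residue(res_id=str(j + 1), coords=atoms(center)))

    structure = ToyStructure(chains={"A": chain_a, "B": chain_b}, name="toy")
    truth_a = {str(i + 1) for i in idx_a}
    truth_b = {str(j + 1) for j in idx_b}
    return structure, (truth_a, truth_b)


def structure_to_pdb(structure: ToyStructure, path: str | Path) -> None:
    """Write a minimal PDB file (glycine CA-style pseudo-atoms)."""
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in structure.chains.items():
            for res in residues:
                for k, coord in enumerate(res.coords):
                    serial += 1
                    name = "CA" if k == 0 else f"C{k}"
                    fh.write(
                        f"ATOM  {serial:5d} {name:<4s} GLY {chain_id:1s}"
                        f"{int(res.res_id):4d}    "
                        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                        f"  1.00  0.00           C\n"
                    )
            fh.write("TER\n")
        fh.write("END\n")
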