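"""Parsing and classification of 3did-style domain-domain interface records.

3did infers domain-domain interface (DDI) types by scanning PDB structures
for pairs of Pfam HMM matches in atomic contact (at least five noncovalent
contacts).  Its flat-file export is block structured: a ``#=ID`` header names
the Pfam pair of a DDI type, each ``#=3D`` line describes one interface
observed in one structure (PDB id, the two chain:range locants, the 3did
score and z-score), and the indented lines that follow list the contacting
residue pairs.  ``//`` closes a block.

This module parses that dialect, groups interfaces into DDI types with a
canonical Pfam-pair identity, classifies each type by its chain and protein
composition (intrachain-only / homo-protein-only / hetero interchain) and
selects one representative interface per structure.  Only the hetero
interchain class — types with at least one interface between two different
proteins — is a sensible candidate set for predicting interactions between
distinct proteins; intrachain-only and homodimer-only evidence cannot be
told apart from crystal packing or intramolecular geometry without curation.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ChainMappingError, FlatParseError, StateError

__all__ = [
    "DDIClass",
    "InterfaceInstance",
    "DDIType",
    "ChainMap",
    "ParseReport",
    "canonical_pair",
    "parse_3did_flat",
    "write_3did_flat",
    "classify_ddi_type",
    "classify_all",
    "select_representatives",
    "best_interface",
    "filter_candidate_set",
    "classification_table",
]

#: minimum number of residue-residue contacts 3did requires to admit an interface
MIN_CONTACTS = 5

_PFAM_AT = re.compile(r"^(?P<acc>[A-Za-z0-9_.-]+?)(?:\.\d+)?@Pfam$")


class DDIClass(enum.Enum):
    """Composition class of a DDI type."""

    INTRACHAIN_ONLY = "intrachain_only"
    HOMOPROTEIN_ONLY = "homoprotein_only"
    HETERO_INTERCHAIN = "hetero_interchain"


def canonical_pair(pfam_a: str, pfam_b: str) -> tuple[str, str]:
    """Order a Pfam pair lexicographically; self-pairs are allowed."""
    return (pfam_a, pfam_b) if pfam_a <= pfam_b else (pfam_b, pfam_a)


@dataclass(frozen=True)
class InterfaceInstance:
    """One observed domain-pair contact in one structure.

    ``contacts`` keeps the residue identifiers as opaque author-numbering
    tokens in file order; numeric interpretation is deferred to the geometry
    layer because PDB author numbering is not monotone.
    """

    pfam_a: str
    pfam_b: str
    pdb_id: str
    chain_a: str
    chain_b: str
    score_3did: float
    zscore_3did: float
    contacts: tuple[tuple[str, str], ...]
    range_a: str = ""
    range_b: str = ""

    def __post_init__(self):
        if not self.chain_a or not self.chain_b:
            raise ValueError("chain identifiers must be non-empty")
        if not (math.isfinite(self.score_3did) and math.isfinite(self.zscore_3did)):
            raise ValueError("3did score and z-score must be finite")
        if len(self.contacts) < MIN_CONTACTS:
            raise ValueError(
                f"interface lists {len(self.contacts)} contacts; "
                f"3did admits interfaces with at least {MIN_CONTACTS}"
            )

    @property
    def intrachain(self) -> bool:
        return self.chain_a == self.chain_b

    def swapped(self) -> "InterfaceInstance":
        """The same interface with the domain order reversed."""
        return InterfaceInstance(
            pfam_a=self.pfam_b,
            pfam_b=self.pfam_a,
            pdb_id=self.pdb_id,
            chain_a=self.chain_b,
            chain_b=self.chain_a,
            score_3did=self.score_3did,
            zscore_3did=self.zscore_3did,
            contacts=tuple((b, a) for a, b in self.contacts),
            range_a=self.range_b,
            range_b=self.range_a,
        )


@dataclass
class DDIType:
    """A Pfam-pair interface type aggregating its observed interfaces."""

    pfam_pair: tuple[str, str]
    interfaces: list[InterfaceInstance]
    ddi_class: DDIClass | None = None

    @property
    def classified(self) -> bool:
        return self.ddi_class is not None

    def interchain_interfaces(self) -> list[InterfaceInstance]:
        return [i for i in self.interfaces if not i.intrachain]

    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for iface in self.interfaces:
            seen.setdefault(iface.pdb_id, None)
        return list(seen)


class ChainMap:
    """Mapping from (pdb_id, chain_id) to a protein accession.

    Unmapped keys are distinguishable from mapped ones: :meth:`lookup`
    raises, :meth:`get` returns ``None``.
    """

    def __init__(self, entries: Mapping[tuple[str, str], str] | None = None):
        self._entries: dict[tuple[str, str], str] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def get(self, pdb_id: str, chain_id: str) -> str | None:
        return self._entries.get((pdb_id, chain_id))

    def lookup(self, pdb_id: str, chain_id: str) -> str:
        try:
            return self._entries[(pdb_id, chain_id)]
        except KeyError:
            raise ChainMappingError([(pdb_id, chain_id)]) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChainMap":
        """Read a chain map from a TSV with columns pdb, chain, accession.

        A header line starting with ``pdb`` is tolerated.
        """
        entries: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FlatParseError(f"chain map row needs 3 columns: {line!r}")
                if parts[0].lower() == "pdb":
                    continue
                entries[(parts[0], parts[1])] = parts[2]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pdb\tchain\taccession\n")
            for (pdb, chain), acc in sorted(self._entries.items()):
                fh.write(f"{pdb}\t{chain}\t{acc}\n")


@dataclass
class ParseReport:
    """Bookkeeping from a flat-file parse: unknown line types and counts."""

    n_types: int = 0
    n_interfaces: int = 0
    unknown_lines: list[tuple[int, str]] = field(default_factory=list)


def _parse_locant(token: str, lineno: int) -> tuple[str, str]:
    """Split a ``chain:range`` locant into (chain, range); range may be empty."""
    if ":" in token:
        chain, rng = token.split(":", 1)
    else:
        chain, rng = token, ""
    if not chain:
        raise FlatParseError(f"empty chain id in locant {token!r}", lineno)
    return chain, rng


def _parse_pfam_token(token: str, lineno: int) -> str:
    token = token.strip("()")
    m = _PFAM_AT.match(token)
    if m:
        return m.group("acc")
    if not token:
        raise FlatParseError("empty Pfam accession in #=ID header", lineno)
    # plain accession, possibly with a version suffix
    return token.split(".")[0] if token.startswith("PF") else token


def parse_3did_flat(
    path: str | Path, report: ParseReport | None = None
) -> list[DDIType]:
    """Parse a 3did-style flat file into DDI types.

    Every ``#=3D`` line becomes one :class:`InterfaceInstance` attached to
    the DDI type of the enclosing ``#=ID`` block; contact lists preserve file
    order; Pfam pairs are canonicalized (lexicographically smaller accession
    first, with chains and contacts swapped accordingly).  Lines of unknown
    type are tolerated and recorded in ``report``.

    Raises :class:`~ddikit.errors.FlatParseError` naming the offending line
    when the block structure is violated.
    """
    path = Path(path)
    types: dict[tuple[str, str], DDIType] = {}
    report = report if report is not None else ParseReport()

    cur_pair: tuple[str, str] | None = None
    cur_swap = False  # header pair was reversed during canonicalization
    # pending interface fields, contacts accumulated until the next boundary
    pending: dict | None = None

    def flush_pending(lineno: int) -> None:
        nonlocal pending
        if pending is None:
            return
        assert cur_pair is not None
        try:
            iface = InterfaceInstance(
                pfam_a=cur_pair[0],
                pfam_b=cur_pair[1],
                pdb_id=pending["pdb"],
                chain_a=pending["chain_a"],
                chain_b=pending["chain_b"],
                score_3did=pending["score"],
                zscore_3did=pending["zscore"],
                contacts=tuple(pending["contacts"]),
                range_a=pending["range_a"],
                range_b=pending["range_b"],
            )
        except ValueError as exc:
            raise FlatParseError(str(exc), pending["lineno"]) from exc
        types[cur_pair].interfaces.append(iface)
        report.n_interfaces += 1
        pending = None

    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#=ID"):
                flush_pending(lineno)
                fields = line.split("\t")
                if len(fields) < 3:
                    fields = line.split()
                if len(fields) < 3:
                    raise FlatParseError("#=ID header needs a Pfam pair", lineno)
                # accept either "#=ID name_a name_b (PFa@Pfam PFb@Pfam)" or
                # "#=ID PFa PFb"
                tokens = [t for t in fields[1:] if t]
                pfam_tokens = [t for t in tokens if "@Pfam" in t]
                if len(pfam_tokens) >= 2:
                    acc_a = _parse_pfam_token(pfam_tokens[0], lineno)
                    acc_b = _parse_pfam_token(pfam_tokens[1], lineno)
                else:
                    if len(tokens) < 2:
                        raise FlatParseError("#=ID header needs two domains", lineno)
                    acc_a = _parse_pfam_token(tokens[-2], lineno)
                    acc_b = _parse_pfam_token(tokens[-1], lineno)
                cur_pair = canonical_pair(acc_a, acc_b)
                cur_swap = (acc_a, acc_b) != cur_pair
                types.setdefault(cur_pair, DDIType(cur_pair, []))
            elif line.startswith("#=3D"):
                flush_pending(lineno)
                if cur_pair is None:
                    raise FlatParseError("#=3D line before any #=ID header", lineno)
                fields = [t for t in re.split(r"\s+", line) if t]
                if len(fields) < 6:
                    raise FlatParseError(
                        "#=3D line needs pdb, two chain locants, score, z-score",
                        lineno,
                    )
                pdb = fields[1].lower()
                chain_a, range_a = _parse_locant(fields[2], lineno)
                chain_b, range_b = _parse_locant(fields[3], lineno)
                try:
                    score = float(fields[4])
                    zscore = float(fields[5])
                except ValueError:
                    raise FlatParseError(
                        f"non-numeric score fields {fields[4]!r} {fields[5]!r}", lineno
                    ) from None
                if cur_swap:
                    chain_a, chain_b = chain_b, chain_a
                    range_a, range_b = range_b, range_a
                pending = {
                    "pdb": pdb,
                    "chain_a": chain_a,
                    "chain_b": chain_b,
                    "range_a": range_a,
                    "range_b": range_b,
                    "score": score,
                    "zscore": zscore,
                    "contacts": [],
                    "lineno": lineno,
                }
            elif line.startswith("//"):
                flush_pending(lineno)
                cur_pair = None
            elif line.startswith("#"):
                # unknown annotation line type: tolerated, recorded
                report.unknown_lines.append((lineno, line))
            else:
                if pending is None:
                    raise FlatParseError(
                        "residue contact line outside an interface block", lineno
                    )
                tokens = [t for t in re.split(r"\t", line.strip()) if t]
                if len(tokens) < 2:
                    tokens = [t for t in line.split() if t]
                if len(tokens) < 2:
                    raise FlatParseError(
                        "contact line needs two residue tokens", lineno
                    )
                res_a, res_b = tokens[0].strip(), tokens[1].strip()
                if cur_swap:
                    res_a, res_b = res_b, res_a
                pending["contacts"].append((res_a, res_b))
        flush_pending(lineno + 1)

    report.n_types = len(types)
    return list(types.values())


def write_3did_flat(types: Iterable[DDIType], path: str | Path) -> None:
    """Serialize DDI types back to the flat dialect (canonical order)."""
    with open(path, "w") as fh:
        for t in types:
            fh.write(f"#=ID\t{t.pfam_pair[0]}\t{t.pfam_pair[1]}\t"
                     f"({t.pfam_pair[0]}@Pfam\t{t.pfam_pair[1]}@Pfam)\n")
            for iface in t.interfaces:
                loc_a = f"{iface.chain_a}:{iface.range_a}" if iface.range_a else iface.chain_a
                loc_b = f"{iface.chain_b}:{iface.range_b}" if iface.range_b else iface.chain_b
                fh.write(
                    f"#=3D\t{iface.pdb_id}\t{loc_a}\t{loc_b}\t"
                    f"{iface.score_3did:g}\t{iface.zscore_3did:g}\n"
                )
                for res_a, res_b in iface.contacts:
                    fh.write(f"{res_a}\t{res_b}\n")
            fh.write("//\n")


def classify_ddi_type(t: DDIType, cmap: ChainMap) -> DDIClass:
    """Classify a DDI type by chain and protein composition.

    A type whose every interface joins a chain to itself is intrachain-only.
    Otherwise the interchain interfaces decide: if every one of them joins
    two chains of the same protein accession the type is homo-protein-only;
    any interface between two different accessions makes it hetero
    interchain.  Interchain interfaces whose chains are absent from ``cmap``
    abort classification loudly — guessing would contaminate the candidate
    set.
    """
    interchain = t.interchain_interfaces()
    if not interchain:
        t.ddi_class = DDIClass.INTRACHAIN_ONLY
        return t.ddi_class

    missing = set()
    for iface in interchain:
        for chain in (iface.chain_a, iface.chain_b):
            if (iface.pdb_id, chain) not in cmap:
                missing.add((iface.pdb_id, chain))
    if missing:
        raise ChainMappingError(missing)

    homo = all(
        cmap.lookup(i.pdb_id, i.chain_a) == cmap.lookup(i.pdb_id, i.chain_b)
        for i in interchain
    )
    t.ddi_class = DDIClass.HOMOPROTEIN_ONLY if homo else DDIClass.HETERO_INTERCHAIN
    return t.ddi_class


def classify_all(types: Iterable[DDIType], cmap: ChainMap) -> dict[DDIClass, int]:
    """Classify every type in place; return counts per class."""
    counts = {c: 0 for c in DDIClass}
    for t in types:
        counts[classify_ddi_type(t, cmap)] += 1
    return counts


def _iface_sort_key(indexed: tuple[int, InterfaceInstance]):
    idx, iface = indexed
    # highest score wins; ties broken lexicographically on chains, then
    # first-seen order, for deterministic regression behaviour
    return (-iface.score_3did, iface.chain_a, iface.chain_b, idx)


def select_representatives(t: DDIType) -> dict[tuple[tuple[str, str], str], InterfaceInstance]:
    """One representative interface per structure of a DDI type.

    Within a structure the interchain interface with the highest 3did score
    is preferred regardless of intrachain scores; only if the structure has
    no interchain interface is the best intrachain interface kept.
    """
    if not t.interfaces:
        raise StateError(f"DDI type {t.pfam_pair} has no interfaces")
    by_pdb: dict[str, list[tuple[int, InterfaceInstance]]] = {}
    for idx, iface in enumerate(t.interfaces):
        by_pdb.setdefault(iface.pdb_id, []).append((idx, iface))
    reps: dict[tuple[tuple[str, str], str], InterfaceInstance] = {}
    for pdb, group in by_pdb.items():
        interchain = [(i, f) for i, f in group if not f.intrachain]
        pool = interchain if interchain else group
        reps[(t.pfam_pair, pdb)] = min(pool, key=_iface_sort_key)[1]
    return reps


def best_interface(t: DDIType) -> InterfaceInstance:
    """The single highest-3did-score interface of a type (deterministic ties)."""
    if not t.interfaces:
        raise StateError(f"DDI type {t.pfam_pair} has no interfaces")
    return min(enumerate(t.interfaces), key=_iface_sort_key)[1]


def filter_candidate_set(types: list[DDIType]) -> list[DDIType]:
    """Retain the hetero-interchain subset, order stable.

    These are the types with interchain evidence and at least one interface
    between two different proteins — the only class usable for predicting
    interfaces between distinct interacting proteins.
    """
    for t in types:
        if not t.classified:
            raise StateError(
                f"DDI type {t.pfam_pair} is unclassified; run classify_ddi_type first"
            )
    return [t for t in types if t.ddi_class is DDIClass.HETERO_INTERCHAIN]


def classification_table(types: Iterable[DDIType]) -> "pandas.DataFrame":
    """Tabulate classified types: pair, counts, class, representatives."""
    import pandas as pd

    rows = []
    for t in types:
        reps = select_representatives(t)
        rep_str = ";".join(
            f"{pdb}:{iface.chain_a}-{iface.chain_b}"
            for (_, pdb), iface in sorted(reps.items())
        )
        rows.append(
            {
                "pfam_a": t.pfam_pair[0],
                "pfam_b": t.pfam_pair[1],
                "n_interfaces": len(t.interfaces),
                "n_structures": len(t.structures()),
                "class": t.ddi_class.value if t.ddi_class else "unclassified",
                "representatives": rep_str,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pfam_a", "pfam_b", "n_interfaces", "n_structures", "class",
            "representatives",
        ],
    )
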