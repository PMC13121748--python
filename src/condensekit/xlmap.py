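"""Mapping of crosslinking-MS identifications onto structure models.

MS-cleavable crosslinkers such as DSBU covalently join K/S/T/Y residues
whose side chains are close in space. Each identified residue pair can be
tested against monomer and dimer structure models by measuring Cα–Cα
distances: a crosslink is *compatible* with a structure when the distance
is at or below a cutoff set by the linker span (30 Å for DSBU). Testing
the pair on the monomer (intra-chain) and on the dimer (inter-chain)
yields five categories: compatible only intra-chain, only inter-chain,
with both, with neither, or no structural information when neither model
resolves the residues.

A special class of identifications — the *homodimer* crosslinks — join
the same residue (more generally, residues on sequence-overlapping tryptic
peptides) and therefore can only arise from two copies of the protein.

The module also aggregates crosslink spectrum matches (XSMs) into
domain-by-domain contact tables and compares conditions by frequency
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "PeptideInterval",
    "CrosslinkRecord",
    "StructureModel",
    "DomainMap",
    "CompatClass",
    "CrossTab",
    "PGL3_DOMAINS",
    "read_crosslink_table",
    "read_structure_model",
    "detect_homodimer",
    "ca_distance",
    "classify_compatibility",
    "classify_records",
    "assign_domains",
    "crosstab",
    "condition_difference",
    "condition_overlap",
    "merge_domains",
]

DEFAULT_CUTOFF_A = 30.0  # Cα–Cα compatibility cutoff for DSBU, Å

#: Default domain boundaries for full-length PGL-3 (693 residues):
#: two folded dimerization domains D1 and D2, the internal disordered
#: region, and the C-terminal RGG region. 1-based inclusive ranges.
PGL3_DOMAINS: list[tuple[str, int, int]] = [
    ("D1", 1, 212),
    ("D2", 213, 447),
    ("IDR", 448, 622),
    ("RGG", 623, 693),
]

#: Residues reactive toward DSBU.
LINKABLE_RESIDUES = frozenset("KSTY")


class SchemaError(ValueError):
    """Input table is missing mandatory columns."""


class ValidationError(ValueError):
    """Rows violate record invariants; message lists offending rows."""


@dataclass(frozen=True, order=True)
class PeptideInterval:
    """1-based closed interval of a tryptic peptide in protein coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid peptide interval [{self.start}, {self.end}]")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "PeptideInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CrosslinkRecord:
    """One crosslinked residue pair with its supporting spectrum count."""

    protein_id: str
    res_a: int
    res_b: int
    aa_a: str
    aa_b: str
    pep_a: PeptideInterval
    pep_b: PeptideInterval
    condition: str = ""
    replicate: str = ""
    n_xsm: int = 1

    def __post_init__(self) -> None:
        problems = []
        if self.res_a not in self.pep_a:
            problems.append(f"res_a={self.res_a} outside pep_a={self.pep_a}")
        if self.res_b not in self.pep_b:
            problems.append(f"res_b={self.res_b} outside pep_b={self.pep_b}")
        if self.n_xsm < 1:
            problems.append(f"n_xsm={self.n_xsm} < 1")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def residue_pair(self) -> tuple[int, int]:
        """Unordered residue pair as a sorted tuple."""
        return tuple(sorted((self.res_a, self.res_b)))  # type: ignore[return-value]


@dataclass
class StructureModel:
    """Residue-indexed Cα coordinates per chain, in Å.

    ``role`` records whether the model represents a monomer (one chain)
    or a dimer (two chains); intra-chain distances are measured on
    monomers, inter-chain distances on dimers.
    """

    chains: dict[str, dict[int, np.ndarray]]
    role: str = "monomer"

    def __post_init__(self) -> None:
        n = len(self.chains)
        if self.role == "monomer" and n != 1:
            raise ValueError(f"monomer model must have exactly 1 chain, got {n}")
        if self.role == "dimer" and n != 2:
            raise ValueError(f"dimer model must have exactly 2 chains, got {n}")
        for label, residues in self.chains.items():
            for pos, xyz in residues.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite Cα coordinate at {label}:{pos}")

    @property
    def chain_labels(self) -> list[str]:
        return list(self.chains)


def read_structure_model(path: str | Path, role: str) -> StructureModel:
    """Load Cα coordinates from a PDB/mmCIF file.

    Only the first model is used; residues without a Cα atom are skipped
    (they count as unresolved for distance purposes).
    """
    st = gemmi.read_structure(str(path))
    chains: dict[str, dict[int, np.ndarray]] = {}
    for chain in st[0]:
        coords: dict[int, np.ndarray] = {}
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is not None:
                coords[residue.seqid.num] = np.array(
                    [ca.pos.x, ca.pos.y, ca.pos.z], dtype=float
                )
        if coords:
            chains[chain.name] = coords
    return StructureModel(chains=chains, role=role)


class DomainMap:
    """Ordered, gap-free partition of residues 1..L into labeled domains."""

    def __init__(self, domains: Sequence[tuple[str, int, int]]):
        if not domains:
            raise ValueError("empty domain map")
        expected_start = 1
        for label, start, end in domains:
            if start != expected_start:
                raise ValueError(
                    f"domain map has a gap or overlap before '{label}' "
                    f"(expected start {expected_start}, got {start})"
                )
            if end < start:
                raise ValueError(f"domain '{label}' has end < start")
            expected_start = end + 1
        self.domains = list(domains)
        self.labels = [d[0] for d in domains]
        self.length = domains[-1][2]

    def assign(self, pos: int) -> str:
        if not (1 <= pos <= self.length):
            raise ValueError(
                f"residue {pos} outside domain map coverage 1..{self.length}"
            )
        for label, start, end in self.domains:
            if start <= pos <= end:
                return label
        raise AssertionError("unreachable: map is a partition")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DomainMap) and self.domains == other.domains

    def __repr__(self) -> str:
        body = ", ".join(f"{l}:{s}-{e}" for l, s, e in self.domains)
        return f"DomainMap({body})"


class CompatClass(str, Enum):
    """Compatibility of a crosslink with monomer/dimer structure models."""

    INTRA_ONLY = "intra_only"
    INTER_ONLY = "inter_only"
    BOTH = "both"
    NEITHER = "neither"
    NO_STRUCTURE = "no_structure"


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "protein",
    "res_a",
    "aa_a",
    "pep_a_start",
    "pep_a_end",
    "res_b",
    "aa_b",
    "pep_b_start",
    "pep_b_end",
)
OPTIONAL_COLUMNS = ("condition", "replicate", "n_xsm")


def read_crosslink_table(
    path: str | Path,
    rename: Mapping[str, str] | None = None,
    zero_based: bool = False,
) -> list[CrosslinkRecord]:
    """Read a crosslink identification CSV into validated records.

    Parameters
    ----------
    path:
        CSV with columns ``protein, res_a, aa_a, pep_a_start, pep_a_end,
        res_b, aa_b, pep_b_start, pep_b_end`` and optionally
        ``condition, replicate, n_xsm``.
    rename:
        Maps column names found in the file to the canonical names above,
        so exports with different headers can be ingested directly.
    zero_based:
        If true, residue and peptide positions in the file are 0-based and
        are shifted by +1 on load; all records are stored 1-based.
    """
    df = pd.read_csv(path)
    if rename:
        df = df.rename(columns=dict(rename))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    shift = 1 if zero_based else 0
    records: list[CrosslinkRecord] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CrosslinkRecord(
                    protein_id=str(row["protein"]),
                    res_a=int(row["res_a"]) + shift,
                    res_b=int(row["res_b"]) + shift,
                    aa_a=str(row["aa_a"]),
                    aa_b=str(row["aa_b"]),
                    pep_a=PeptideInterval(
                        int(row["pep_a_start"]) + shift, int(row["pep_a_end"]) + shift
                    ),
                    pep_b=PeptideInterval(
                        int(row["pep_b_start"]) + shift, int(row["pep_b_end"]) + shift
                    ),
                    condition=str(row["condition"]) if "condition" in df.columns else "",
                    replicate=str(row["replicate"]) if "replicate" in df.columns else "",
                    n_xsm=int(row["n_xsm"]) if "n_xsm" in df.columns else 1,
                )
            )
        except (ValueError, ValidationError) as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if bad_rows:
        raise ValidationError(
            f"{len(bad_rows)} invalid row(s):\n" + "\n".join(bad_rows)
        )
    return records


# ---------------------------------------------------------------------------
# Homodimer detection
# ---------------------------------------------------------------------------

def detect_homodimer(records: Iterable[CrosslinkRecord]) -> list[bool]:
    """Flag crosslinks that must be intermolecular.

    Because tryptic fragments of a single-protein digest are unique in
    sequence, a crosslink between peptides that overlap in sequence (the
    canonical case being the same residue linked to itself) cannot come
    from one molecule: it marks a homodimer contact. The flag is true iff
    the two peptide intervals share at least one position.
    """
    return [rec.pep_a.overlaps(rec.pep_b) for rec in records]


# ---------------------------------------------------------------------------
# Distances and compatibility
# ---------------------------------------------------------------------------

def ca_distance(
    model: StructureModel, mode: str, res_i: int, res_j: int
) -> float | None:
    """Cα–Cα distance in Å, or ``None`` if either residue is unresolved.

    ``mode='intra'`` measures within a single chain (the first chain of
    the model). ``mode='inter'`` requires a dimer and takes the minimum
    over the two cross-chain pairings d(i@A, j@B) and d(i@B, j@A), so the
    result does not depend on chain labeling.
    """
    if mode == "intra":
        chain = model.chains[model.chain_labels[0]]
        if res_i not in chain or res_j not in chain:
            return None
        return float(np.linalg.norm(chain[res_i] - chain[res_j]))
    if mode == "inter":
        if len(model.chains) != 2:
            raise ValueError("inter-chain distance requires a dimer model")
        a, b = (model.chains[l] for l in model.chain_labels)
        dists = []
        if res_i in a and res_j in b:
            dists.append(float(np.linalg.norm(a[res_i] - b[res_j])))
        if res_i in b and res_j in a:
            dists.append(float(np.linalg.norm(b[res_i] - a[res_j])))
        return min(dists) if dists else None
    raise ValueError(f"unknown mode {mode!r}; use 'intra' or 'inter'")


def classify_compatibility(
    record: CrosslinkRecord,
    monomer: StructureModel | None,
    dimer: StructureModel | None,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> CompatClass:
    """Classify a crosslink against monomer and dimer structure models.

    A distance at or below ``cutoff`` is compatible (ties at exactly the
    cutoff count as compatible). If one of the two distances cannot be
    measured (residue unresolved or model absent), classification falls
    back on the available one; only when both are missing is the result
    ``NO_STRUCTURE``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d_intra = (
        ca_distance(monomer, "intra", record.res_a, record.res_b)
        if monomer is not None
        else None
    )
    d_inter = (
        ca_distance(dimer, "inter", record.res_a, record.res_b)
        if dimer is not None
        else None
    )
    if d_intra is None and d_inter is None:
        return CompatClass.NO_STRUCTURE
    intra_ok = d_intra is not None and d_intra <= cutoff
    inter_ok = d_inter is not None and d_inter <= cutoff
    if intra_ok and inter_ok:
        return CompatClass.BOTH
    if intra_ok:
        return CompatClass.INTRA_ONLY
    if inter_ok:
        return CompatClass.INTER_ONLY
    return CompatClass.NEITHER


def classify_records(
    records: Sequence[CrosslinkRecord],
    monomer: StructureModel | None,
    dimer: StructureModel | None,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> pd.DataFrame:
    """Per-record classification table (one row per crosslink).

    Columns include both measured distances, the compatibility class, the
    homodimer flag, and a ``one_sided`` audit flag marking records that
    were classified with only one of the two distances available.
    """
    homodimer = detect_homodimer(records)
    rows = []
    for rec, homo in zip(records, homodimer):
        d_intra = (
            ca_distance(monomer, "intra", rec.res_a, rec.res_b)
            if monomer is not None
            else None
        )
        d_inter = (
            ca_distance(dimer, "inter", rec.res_a, rec.res_b)
            if dimer is not None
            else None
        )
        cls = classify_compatibility(rec, monomer, dimer, cutoff)
        rows.append(
            {
                "protein": rec.protein_id,
                "res_a": rec.res_a,
                "res_b": rec.res_b,
                "condition": rec.condition,
                "n_xsm": rec.n_xsm,
                "d_intra_A": d_intra,
                "d_inter_A": d_inter,
                "class": cls.value,
                "homodimer": homo,
                "one_sided": (d_intra is None) != (d_inter is None),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Domain crosstabs
# ---------------------------------------------------------------------------

def assign_domains(
    record: CrosslinkRecord, dmap: DomainMap
) -> tuple[str, str]:
    """Unordered domain-label pair for a crosslink, in domain-map order."""
    a = dmap.assign(record.res_a)
    b = dmap.assign(record.res_b)
    order = {label: i for i, label in enumerate(dmap.labels)}
    return (a, b) if order[a] <= order[b] else (b, a)


@dataclass
class CrossTab:
    """Square domain-by-domain contact table.

    The upper triangle (including the diagonal) is canonical; the matrix
    is stored symmetric for display. ``mode`` is ``counts`` (XSM sums),
    ``frequencies`` (counts / total XSMs) or ``difference``.
    """

    table: pd.DataFrame
    mode: str
    total_xsm: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(self.table.index)

    def upper_triangle_sum(self) -> float:
        m = self.table.to_numpy()
        return float(np.triu(m).sum())

    def value(self, dom_a: str, dom_b: str) -> float:
        return float(self.table.loc[dom_a, dom_b])


def crosstab(
    records: Sequence[CrosslinkRecord],
    dmap: DomainMap,
    mode: str = "counts",
    condition: str | None = None,
    unique_pairs: bool = False,
) -> CrossTab:
    """Aggregate crosslinks into a domain-by-domain contact table.

    Counts sum the supporting spectrum count ``n_xsm`` of every record
    whose residues fall in the given domain pair (replicates included by
    simply listing their records). With ``unique_pairs=True`` each unique
    (res_a, res_b) pair counts once instead, the unique-pair view of the
    same data. Frequencies divide counts by the total.
    """
    if mode not in ("counts", "frequencies"):
        raise ValueError(f"unknown crosstab mode {mode!r}")
    if condition is not None:
        records = [r for r in records if r.condition == condition]
    if mode == "frequencies" and (
        not records or sum(r.n_xsm for r in records) == 0
    ):
        raise ValueError("cannot normalize frequencies: no records/XSMs")

    n = len(dmap.labels)
    mat = np.zeros((n, n), dtype=float)
    index = {label: i for i, label in enumerate(dmap.labels)}
    seen_pairs: set[tuple[int, int]] = set()
    total = 0
    for rec in records:
        if unique_pairs:
            if rec.residue_pair in seen_pairs:
                continue
            seen_pairs.add(rec.residue_pair)
            weight = 1
        else:
            weight = rec.n_xsm
        a, b = assign_domains(rec, dmap)
        mat[index[a], index[b]] += weight
        total += weight
    if mode == "frequencies":
        mat = mat / total
    # mirror the canonical upper triangle
    sym = np.triu(mat) + np.triu(mat, k=1).T
    table = pd.DataFrame(sym, index=dmap.labels, columns=dmap.labels)
    return CrossTab(table=table, mode=mode, total_xsm=total, labels=list(dmap.labels))


def condition_difference(tab_a: CrossTab, tab_b: CrossTab) -> CrossTab:
    """Entrywise frequency difference a − b between two conditions.

    Positive entries mark domain pairs crosslinked at higher frequency in
    condition a. Upper-triangle entries sum to zero by construction.
    """
    if tab_a.mode != "frequencies" or tab_b.mode != "frequencies":
        raise ValueError("condition_difference requires frequency tables")
    if tab_a.labels != tab_b.labels:
        raise ValueError("crosstabs built on different domain maps")
    diff = tab_a.table - tab_b.table
    return CrossTab(
        table=diff,
        mode="difference",
        total_xsm=tab_a.total_xsm + tab_b.total_xsm,
        labels=list(tab_a.labels),
    )


def merge_domains(tab: CrossTab, groups: Mapping[str, str]) -> CrossTab:
    """Aggregate a crosstab into super-domains (e.g. D1+D2 vs IDR+RGG).

    ``groups`` maps each original domain label to a super-domain label.
    Upper-triangle entries are re-binned so totals are conserved.
    """
    missing = [l for l in tab.labels if l not in groups]
    if missing:
        raise ValueError(f"no super-domain for label(s): {missing}")
    super_labels = list(dict.fromkeys(groups[l] for l in tab.labels))
    index = {label: i for i, label in enumerate(super_labels)}
    n = len(super_labels)
    mat = np.zeros((n, n), dtype=float)
    src = tab.table.to_numpy()
    for i, li in enumerate(tab.labels):
        for j in range(i, len(tab.labels)):
            lj = tab.labels[j]
            a, b = sorted((index[groups[li]], index[groups[lj]]))
            mat[a, b] += src[i, j]
    sym = np.triu(mat) + np.triu(mat, k=1).T
    table = pd.DataFrame(sym, index=super_labels, columns=super_labels)
    return CrossTab(table=table, mode=tab.mode, total_xsm=tab.total_xsm, labels=super_labels)


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def condition_overlap(
    records_a: Iterable[CrosslinkRecord],
    records_b: Iterable[CrosslinkRecord],
) -> tuple[set[tuple[int, int]], set[tuple[int, int]], set[tuple[int, int]]]:
    """Partition unique residue pairs into (shared, only_a, only_b)."""
    pairs_a = {r.residue_pair for r in records_a}
    pairs_b = {r.residue_pair for r in records_b}
    return pairs_a & pairs_b, pairs_a - pairs_b, pairs_b - pairs_a
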