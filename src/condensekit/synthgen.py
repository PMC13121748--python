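"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its parameters and a seed, so
regenerating with the same arguments reproduces identical outputs. The
generators emulate the experimental data the analysis modules consume:

- toy protein structures with deterministic line/offset geometry, so
  every Cα–Cα distance is hand-checkable;
- crosslink identification tables with realistic tryptic peptide fields
  and known compatibility classes and homodimer status;
- 2D Brownian bead trajectories at a chosen diffusion coefficient;
- two-channel condensate images with a known dense:dilute probe ratio;
- single-exponential FRAP traces (a test-harness model: recovery depth
  and rate are the ground truth, not a mechanistic claim);
- 1:1 Langmuir BLI sensorgrams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import tifffile
from skimage import filters as _skfilters

from . import binding as _binding
from . import imaging as _imaging
from . import rheo as _rheo
from . import xlmap as _xlmap
from .xlmap import LINKABLE_RESIDUES, PeptideInterval, StructureModel

__all__ = [
    "GroundTruth",
    "InfeasibleRequestError",
    "make_toy_structure",
    "toy_sequence",
    "digest_protein",
    "simulate_crosslinks",
    "simulate_trajectories",
    "simulate_condensate_field",
    "simulate_frap",
    "simulate_sensorgrams",
    "write_trajectory_csv",
    "write_crosslink_csv",
    "write_image_tiff",
    "write_frap_csv",
    "write_sensorgram_csv",
    "write_pdb",
    "write_ground_truth",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Digest defaults mirroring a standard fully-specific tryptic search:
# peptide length 6-60, up to 3 missed cleavages.
DIGEST_MIN_LEN = 6
DIGEST_MAX_LEN = 60
DIGEST_MAX_MISSED = 3


class InfeasibleRequestError(ValueError):
    """The requested synthetic records cannot exist in the given geometry."""


@dataclass
class GroundTruth:
    """True parameters behind one synthetic dataset."""

    kind: str  # trajectory | crosslink | image | frap | sensorgram
    params: dict
    seed: int


# ---------------------------------------------------------------------------
# Toy structures and digestion
# ---------------------------------------------------------------------------

def make_toy_structure(
    n_res_per_chain: int,
    n_chains: int = 1,
    spacing: float = 3.8,
    offset: float = 20.0,
) -> StructureModel:
    """Deterministic line geometry: residue i of chain A at x=(i−1)·spacing.

    With two chains, chain B is a rigid copy translated by ``offset`` Å
    along y, so d(Cα_i^A, Cα_i^B) = offset for every i. No randomness:
    all distances are closed-form, which keeps compatibility classes
    hand-checkable.
    """
    if n_chains not in (1, 2):
        raise ValueError(f"unsupported geometry: n_chains must be 1 or 2, got {n_chains}")
    if n_res_per_chain < 2:
        raise ValueError("need at least 2 residues per chain")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    chain_a = {
        i: np.array([(i - 1) * spacing, 0.0, 0.0]) for i in range(1, n_res_per_chain + 1)
    }
    chains = {"A": chain_a}
    if n_chains == 2:
        chains["B"] = {i: xyz + np.array([0.0, offset, 0.0]) for i, xyz in chain_a.items()}
    return StructureModel(chains=chains, role="monomer" if n_chains == 1 else "dimer")


#: Sequence block whose tryptic digest yields 8-residue peptides, each
#: containing one of every DSBU-reactive residue type (K, S, T, Y).
_TOY_BLOCK = "SAGTAYAK"


def toy_sequence(n_res: int) -> str:
    """Repeating-block sequence of length ``n_res`` rich in K/S/T/Y."""
    reps = n_res // len(_TOY_BLOCK) + 1
    return (_TOY_BLOCK * reps)[:n_res]


def digest_protein(
    sequence: str,
    max_missed: int = DIGEST_MAX_MISSED,
    min_len: int = DIGEST_MIN_LEN,
    max_len: int = DIGEST_MAX_LEN,
) -> list[PeptideInterval]:
    """Tryptic peptides as 1-based closed intervals.

    Cleaves after K or R unless the next residue is P; emits all
    missed-cleavage variants up to ``max_missed``, filtered to
    [min_len, max_len]. Used to give synthetic crosslink records
    realistic peptide fields.
    """
    if not sequence:
        return []
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"sequence contains non-amino-acid letters: {sorted(bad)}")
    n = len(sequence)
    # cut points: cleavage after position i (1-based) when seq[i-1] in KR
    # and seq[i] != P; sequence end is always a boundary.
    cuts = [
        i
        for i in range(1, n)
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ] + [n]
    starts = [1] + [c + 1 for c in cuts[:-1]]
    peptides: list[PeptideInterval] = []
    for i, start in enumerate(starts):
        for missed in range(max_missed + 1):
            if i + missed >= len(cuts):
                break
            end = cuts[i + missed]
            if min_len <= end - start + 1 <= max_len:
                peptides.append(PeptideInterval(start, end))
    return peptides


# ---------------------------------------------------------------------------
# Crosslink tables
# ---------------------------------------------------------------------------

def _true_class(
    structure: StructureModel, res_i: int, res_j: int, cutoff: float
) -> str:
    """Compatibility class of a residue pair directly from the geometry."""
    chain_a = structure.chains[structure.chain_labels[0]]
    monomer = StructureModel(chains={"A": chain_a}, role="monomer")
    dimer = structure if structure.role == "dimer" else None
    d_intra = _xlmap.ca_distance(monomer, "intra", res_i, res_j)
    d_inter = (
        _xlmap.ca_distance(dimer, "inter", res_i, res_j) if dimer is not None else None
    )
    intra_ok = d_intra is not None and d_intra <= cutoff
    inter_ok = d_inter is not None and d_inter <= cutoff
    if d_intra is None and d_inter is None:
        return "no_structure"
    if intra_ok and inter_ok:
        return "both"
    if intra_ok:
        return "intra_only"
    if inter_ok:
        return "inter_only"
    return "neither"


def simulate_crosslinks(
    structure: StructureModel,
    counts: Mapping[str, int],
    cutoff: float = 30.0,
    seed: int = 0,
    sequence: str | None = None,
    protein_id: str = "TOY",
    condition: str = "125mM",
    replicate: str = "1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a crosslink identification table with known ground truth.

    ``counts`` maps a class to the number of records wanted; classes are
    the compatibility classes (``intra_only``, ``inter_only``, ``both``,
    ``neither``) plus ``homodimer`` (same residue on both sides, carried
    on the same peptide — necessarily intermolecular). Linked residues
    are restricted to K/S/T/Y, and each record carries the tryptic
    peptide containing its residue. Classes the geometry cannot produce
    raise :class:`InfeasibleRequestError` — e.g. inter-only links are
    impossible on a translated-copy dimer, where the cross-chain distance
    never undercuts the within-chain one.
    """
    rng = np.random.default_rng(seed)
    n_res = len(structure.chains[structure.chain_labels[0]])
    if sequence is None:
        sequence = toy_sequence(n_res)
    if len(sequence) != n_res:
        raise ValueError("sequence length must match structure residue count")

    peptides = digest_protein(sequence, max_missed=0)
    pep_of: dict[int, PeptideInterval] = {}
    for pep in peptides:
        for pos in range(pep.start, pep.end + 1):
            pep_of.setdefault(pos, pep)
    linkable = sorted(
        pos for pos in pep_of if sequence[pos - 1] in LINKABLE_RESIDUES
    )

    # enumerate candidate pairs per class
    by_class: dict[str, list[tuple[int, int]]] = {}
    for ai in range(len(linkable)):
        for bi in range(ai + 1, len(linkable)):
            i, j = linkable[ai], linkable[bi]
            cls = _true_class(structure, i, j, cutoff)
            by_class.setdefault(cls, []).append((i, j))
    homodimer_candidates = [(i, i) for i in linkable]

    rows = []
    true_classes: list[str] = []
    homodimer_flags: list[bool] = []

    def add_record(i: int, j: int, homodimer: bool) -> None:
        pep_a, pep_b = pep_of[i], pep_of[j]
        rows.append(
            {
                "protein": protein_id,
                "res_a": i,
                "aa_a": sequence[i - 1],
                "pep_a_start": pep_a.start,
                "pep_a_end": pep_a.end,
                "res_b": j,
                "aa_b": sequence[j - 1],
                "pep_b_start": pep_b.start,
                "pep_b_end": pep_b.end,
                "condition": condition,
                "replicate": replicate,
                "n_xsm": int(rng.integers(1, 6)),
            }
        )
        true_classes.append(_true_class(structure, i, j, cutoff))
        homodimer_flags.append(homodimer)

    for cls, n in counts.items():
        if n <= 0:
            continue
        if cls == "homodimer":
            pool = homodimer_candidates
        else:
            pool = by_class.get(cls, [])
        if len(pool) < n:
            raise InfeasibleRequestError(
                f"requested {n} {cls!r} record(s) but only {len(pool)} "
                f"candidate pair(s) exist in this geometry"
            )
        chosen = rng.choice(len(pool), size=n, replace=False)
        for k in sorted(chosen):
            i, j = pool[int(k)]
            add_record(i, j, homodimer=(cls == "homodimer"))

    table = pd.DataFrame(rows)
    gt = GroundTruth(
        kind="crosslink",
        params={
            "cutoff": cutoff,
            "counts": dict(counts),
            "true_class": true_classes,
            "homodimer": homodimer_flags,
            "protein_id": protein_id,
        },
        seed=seed,
    )
    return table, gt


# ---------------------------------------------------------------------------
# Bead trajectories
# ---------------------------------------------------------------------------

def simulate_trajectories(
    D: float,
    dt: float = 0.15,
    n_frames: int = 100,
    n_particles: int = 25,
    loc_noise_sd: float = 0.0,
    seed: int = 0,
    condensate_id: str = "",
) -> _rheo.TrajectorySet:
    """2D Brownian tracks: per-axis steps with variance 2·D·dt.

    Optional Gaussian localization noise (sd in µm) is added to every
    recorded position; it offsets the MSD by 4·sd² without changing the
    underlying diffusion.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(2.0 * D * dt)
    frames = np.arange(n_frames)
    tracks = {}
    fdict = {}
    for p in range(n_particles):
        steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if loc_noise_sd > 0:
            pos = pos + rng.normal(0.0, loc_noise_sd, size=pos.shape)
        pid = f"p{p}"
        tracks[pid] = pos
        fdict[pid] = frames.copy()
    return _rheo.TrajectorySet(
        tracks=tracks, frames=fdict, dt=dt, condensate_id=condensate_id
    )


# ---------------------------------------------------------------------------
# Condensate images
# ---------------------------------------------------------------------------

def simulate_condensate_field(
    n_condensates: int = 50,
    radius_range: tuple[int, int] = (5, 9),
    pc_true: float = 1.3,
    dilute_level: float = 200.0,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.1,
    ref_background: float = 100.0,
    ref_dense: float = 1000.0,
    cell_margin: int = 18,
    max_size: int = 2048,
) -> tuple[_imaging.ImageField, np.ndarray]:
    """Two-channel image with disk condensates at a known partition ratio.

    The reference channel marks condensates (bright disks on a dim
    background); the probe channel is ``dilute_level`` everywhere and
    ``pc_true × dilute_level`` inside the disks before blur and noise, so
    the true dense:dilute ratio is exactly ``pc_true``. Disks are placed
    on a jittered grid — one per cell, clear of the border and of each
    other with room for dilute annuli — and the true disk label image is
    returned alongside the field.
    """
    if pc_true <= 0:
        raise ValueError("pc_true must be positive")
    rmin, rmax = radius_range
    if not (1 <= rmin <= rmax):
        raise ValueError("invalid radius range")
    rng = np.random.default_rng(seed)

    cell = 2 * rmax + cell_margin
    n_side = int(np.ceil(np.sqrt(n_condensates)))
    size = n_side * cell + cell  # one extra cell of border padding
    max_cells = n_side * n_side
    if size > max_size:
        raise ValueError(
            f"cannot place {n_condensates} non-overlapping disks of radius "
            f"<= {rmax} px within a {max_size} px image"
        )

    ref = np.full((size, size), ref_background, dtype=float)
    probe = np.full((size, size), dilute_level, dtype=float)
    labels = np.zeros((size, size), dtype=int)
    yy, xx = np.mgrid[0:size, 0:size]

    cell_ids = rng.permutation(max_cells)[:n_condensates]
    jitter_max = cell_margin // 2 - 1
    for lab, cid in enumerate(cell_ids, start=1):
        row, col = divmod(int(cid), n_side)
        cy = cell // 2 + cell // 2 + row * cell  # half-cell border padding
        cx = cell // 2 + cell // 2 + col * cell
        cy += int(rng.integers(-jitter_max, jitter_max + 1))
        cx += int(rng.integers(-jitter_max, jitter_max + 1))
        r = int(rng.integers(rmin, rmax + 1))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[disk] = lab
        ref[disk] = ref_dense
        probe[disk] = pc_true * dilute_level

    if blur_sigma > 0:
        ref = _skfilters.gaussian(ref, sigma=blur_sigma, preserve_range=True)
        probe = _skfilters.gaussian(probe, sigma=blur_sigma, preserve_range=True)
    if noise_sd > 0:
        ref = ref + rng.normal(0.0, noise_sd, size=ref.shape)
        probe = probe + rng.normal(0.0, noise_sd, size=probe.shape)
    ref = np.clip(ref, 0.0, None)
    probe = np.clip(probe, 0.0, None)

    field = _imaging.ImageField(
        channels={"reference": ref, "probe": probe}, pixel_size=pixel_size
    )
    return field, labels


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def simulate_frap(
    recovery_fraction: float,
    tau: float,
    n_pre: int = 5,
    n_post: int = 60,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    prebleach_level: float = 100.0,
    bleach_depth: float = 0.75,
    reference_decay: float = 0.0,
) -> _imaging.FrapTrace:
    """Single-exponential FRAP trace with known recovery depth and rate.

    The bleached ROI sits at ``prebleach_level`` before the bleach, drops
    by ``bleach_depth`` of its intensity at the bleach, and recovers as
    f·(1 − e^{−t/τ}) of the lost intensity, so the double-normalized
    curve plateaus at exactly ``recovery_fraction``. The unbleached
    reference is constant, optionally with an exponential acquisition
    photobleaching decay (rate per frame) applied to both channels.
    ``noise_sd`` is a fraction of the prebleach level.
    """
    if not (0.0 <= recovery_fraction <= 1.0):
        raise ValueError("recovery_fraction must be in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    time = np.arange(n) * dt
    t_post = time[n_pre:] - time[n_pre]  # 0 at the first post-bleach frame

    bleach_level = prebleach_level * (1.0 - bleach_depth)
    recovery = recovery_fraction * (1.0 - np.exp(-t_post / tau))
    bleached = np.concatenate(
        [
            np.full(n_pre, prebleach_level),
            bleach_level + (prebleach_level - bleach_level) * recovery,
        ]
    )
    reference = np.full(n, prebleach_level)
    if reference_decay > 0:
        decay = np.exp(-reference_decay * np.arange(n))
        bleached = bleached * decay
        reference = reference * decay
    if noise_sd > 0:
        bleached = bleached + rng.normal(0, noise_sd * prebleach_level, size=n)
    return _imaging.FrapTrace(
        time=time, bleached=bleached, reference=reference, bleach_frame=n_pre
    )


# ---------------------------------------------------------------------------
# BLI sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgrams(
    k_on: float,
    k_off: float,
    R_max: float,
    concentrations: Sequence[float],
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[_binding.Sensorgram]:
    """1:1 Langmuir sensorgrams, one per analyte concentration.

    Association runs from t = 0 to ``t_assoc`` toward the equilibrium
    response R_max·C/(C+K_D); dissociation continues to
    ``t_assoc + t_dissoc`` with single-exponential decay, continuous at
    the boundary.
    """
    if k_on <= 0 or k_off <= 0 or R_max <= 0:
        raise ValueError("k_on, k_off and R_max must be positive")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for c in concentrations:
        if c <= 0:
            raise ValueError("analyte concentrations must be positive")
        resp = _binding.model_1to1(time, c, t_assoc, k_on, k_off, R_max)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        out.append(
            _binding.Sensorgram(
                time=time.copy(), response=resp, concentration=c, t_dissoc=t_assoc
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_trajectory_csv(ts: _rheo.TrajectorySet, path: str | Path) -> None:
    rows = []
    for pid in ts.tracks:
        for f, (x, y) in zip(ts.frames[pid], ts.tracks[pid]):
            rows.append(
                {"particle_id": pid, "frame": int(f), "x_um": x, "y_um": y, "dt_s": ts.dt}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_crosslink_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_image_tiff(field: _imaging.ImageField, path: str | Path) -> None:
    """Write channels as a (C, Y, X) stack with channel names in metadata."""
    names = list(field.channels)
    stack = np.stack([field.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        stack,
        metadata={"channels": names, "pixel_size_um": field.pixel_size},
    )


def write_frap_csv(trace: _imaging.FrapTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "bleached": trace.bleached,
            "reference": trace.reference,
            "bleach_frame": trace.bleach_frame,
        }
    ).to_csv(path, index=False)


def write_sensorgram_csv(
    sensorgrams: Sequence[_binding.Sensorgram], path: str | Path
) -> None:
    frames = []
    for s in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.time,
                    "response": s.response,
                    "concentration_M": s.concentration,
                    "t_dissoc_s": s.t_dissoc,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a Cα-only PDB of a toy structure (residues as ALA)."""
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    for label, residues in structure.chains.items():
        chain = gemmi.Chain(label)
        for pos in sorted(residues):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(pos, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = residues[pos]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Sidecar JSON with the true parameters of a synthetic dataset."""
    Path(path).write_text(json.dumps(asdict(gt), indent=2, default=float))
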