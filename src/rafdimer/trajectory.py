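"""Per-frame descriptor series and their distribution summaries.

A trajectory is a topology (:class:`~rafdimer.structure_io.KinaseStructure`)
plus an ``(n_frames, n_atoms, 3)`` coordinate array in the topology's flat
atom order.  Multi-model PDB files are read natively; DCD/XTC are read
through MDAnalysis when it is installed.

Analysis mirrors standard MD practice for this system: the equilibration
head of each replica is discarded (default: the first 40 % of frames, i.e.
the last 3 μs of a 5 μs run are kept), per-frame descriptors are computed
with the same definitions as for static structures, distributions are
density-normalised 50-bin histograms pooled over replicas (and over both
protomers for dimers), and state probabilities are reported as the mean ±
sample standard deviation over replicas (n = 3 in the reference setup).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .descriptors import DescriptorUnavailableError
from .structure_io import KinaseStructure, read_structure, structure_from_gemmi, to_gemmi

__all__ = [
    "TRIM_FRACTION",
    "N_BINS",
    "Trajectory",
    "DescriptorSeries",
    "HistogramSummary",
    "ProbabilityEstimate",
    "Density2D",
    "EmptyDataError",
    "AlignmentError",
    "read_trajectory",
    "write_multimodel_pdb",
    "extract_series",
    "histogram",
    "state_probability",
    "density2d",
]

TRIM_FRACTION = 0.4  # discard the first 40 % of each replica (keep last 3/5)
N_BINS = 50


class EmptyDataError(ValueError):
    """An operation received no frames or no finite values."""


class AlignmentError(ValueError):
    """Trajectory frames do not match the topology's atoms."""


@dataclass
class Trajectory:
    """Coordinates for every frame, in the topology's flat atom order."""

    topology: KinaseStructure
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    replica_id: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n_atoms = len(self.topology.flat_atoms())
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n_atoms, 3):
            raise AlignmentError(
                f"coordinate array of shape {self.coords.shape} does not match "
                f"topology with {n_atoms} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_structure(self, i: int) -> KinaseStructure:
        return self.topology.with_coordinates(self.coords[i])

    def concatenated(self, other: "Trajectory") -> "Trajectory":
        if other.coords.shape[1:] != self.coords.shape[1:]:
            raise AlignmentError("cannot concatenate trajectories with different atom counts")
        return Trajectory(self.topology, np.concatenate([self.coords, other.coords]), self.replica_id)


def read_trajectory(
    path: str | Path,
    topology: KinaseStructure | str | Path,
    replica_id: int = 0,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, or DCD/XTC via MDAnalysis).

    Frames are mapped to the topology's atoms by (chain, residue number,
    atom name) for multi-model PDB and by file order for binary formats.
    """
    path = Path(path)
    if not isinstance(topology, KinaseStructure):
        topology = read_structure(topology)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return _read_multimodel_pdb(path, topology, replica_id)
    if suffix in (".dcd", ".xtc", ".trr"):
        return _read_mda(path, topology, replica_id)
    raise ValueError(f"unsupported trajectory format {suffix!r}")


def _read_multimodel_pdb(path: Path, topology: KinaseStructure, replica_id: int) -> Trajectory:
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyDataError(f"{path.name}: no models found")
    index = topology.atom_index()
    n_atoms = len(index)
    frames = np.empty((len(st), n_atoms, 3))
    for m, _model in enumerate(st):
        frame = structure_from_gemmi(st, source_id=path.stem, model_index=m)
        got = 0
        for a in frame.flat_atoms():
            key = (a.chain_id, a.residue_number, a.atom_name)
            i = index.get(key)
            if i is None:
                raise AlignmentError(f"{path.name} model {m + 1}: atom {key} absent from topology")
            frames[m, i] = a.coords
            got += 1
        if got != n_atoms:
            raise AlignmentError(
                f"{path.name} model {m + 1}: {got} atoms mapped, topology has {n_atoms}"
            )
    return Trajectory(topology, frames, replica_id)


def _read_mda(path: Path, topology: KinaseStructure, replica_id: int) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading DCD/XTC requires MDAnalysis") from exc
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
        top_path = fh.name
    to_gemmi(topology).write_pdb(top_path)
    u = mda.Universe(top_path, str(path))
    n_atoms = len(topology.flat_atoms())
    if len(u.atoms) != n_atoms:
        raise AlignmentError(
            f"{path.name}: {len(u.atoms)} atoms in trajectory, topology has {n_atoms}"
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return Trajectory(topology, frames, replica_id)


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write every frame as one MODEL of a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = trajectory.topology.source_id or "rafdimer"
    for m in range(trajectory.n_frames):
        frame = to_gemmi(trajectory.frame_structure(m), model_name=str(m + 1))
        st.add_model(frame[0])
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# descriptor series


@dataclass
class DescriptorSeries:
    """Per-frame descriptors for one protomer of one replica."""

    replica_id: int
    protomer_id: str
    frame_index: np.ndarray
    alpha_c_distance: np.ndarray
    dfg_dihedral: np.ndarray
    ke_no_distance: np.ndarray
    ligand_glu501_min_distance: np.ndarray | None = None
    trim_policy: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        for name in ("alpha_c_distance", "dfg_dihedral", "ke_no_distance"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name}: non-finite values in series")


def _torsion_batch(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("...i,...i", n1, n2)
    y = -np.einsum("...i,...i", m1, n2)
    return np.degrees(np.arctan2(y, x)) % 360.0


def extract_series(
    trajectory: Trajectory,
    trim_fraction: float = TRIM_FRACTION,
    ligand_donor_atoms: dict[str, tuple[str, ...]] | None = None,
) -> list[DescriptorSeries]:
    """Descriptor time series per protomer, equilibration head discarded.

    ``floor(trim_fraction * n_frames)`` leading frames are dropped from each
    replica.  The ligand–Glu501 distance is the minimum heavy-atom distance
    between the Glu501 carboxylate oxygens and the ligand's donor-group
    atoms (by default the annotated donor set; override per het-code with
    *ligand_donor_atoms*).  Protomers without a ligand leave that series
    unavailable (``None``).
    """
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    n = trajectory.n_frames
    if n == 0:
        raise EmptyDataError("trajectory has no frames")
    start = int(np.floor(trim_fraction * n))
    idx = np.arange(start, n)
    coords = trajectory.coords[start:]
    topo = trajectory.topology
    index = topo.atom_index()

    def pos(chain, resnum, name):
        key = (chain, resnum, name)
        if key not in index:
            raise DescriptorUnavailableError(f"topology lacks atom {key}")
        return coords[:, index[key], :]

    out: list[DescriptorSeries] = []
    for protomer in topo.protomers:
        cid = protomer.chain_id
        center = (pos(cid, 500, "CA") + pos(cid, 501, "CA") + pos(cid, 502, "CA")) / 3.0
        alpha_c = np.linalg.norm(pos(cid, 582, "CA") - center, axis=-1)
        dihedral = _torsion_batch(
            pos(cid, 592, "CA"), pos(cid, 593, "CA"), pos(cid, 594, "CA"), pos(cid, 595, "CA")
        )
        nz = pos(cid, 483, "NZ")
        ke = np.minimum(
            np.linalg.norm(nz - pos(cid, 501, "OE1"), axis=-1),
            np.linalg.norm(nz - pos(cid, 501, "OE2"), axis=-1),
        )
        lig_series = None
        ligands = topo.ligands_on_chain(cid)
        if ligands:
            lig = ligands[0]
            donors = None
            if ligand_donor_atoms and lig.residue_name in ligand_donor_atoms:
                donors = tuple(ligand_donor_atoms[lig.residue_name])
            elif lig.donor_atoms:
                donors = tuple(sorted(lig.donor_atoms))
            if donors:
                donor_pos = np.stack(
                    [coords[:, index[(cid, lig.residue_number, d)], :] for d in donors], axis=1
                )
                carbox = np.stack([pos(cid, 501, "OE1"), pos(cid, 501, "OE2")], axis=1)
                d = np.linalg.norm(donor_pos[:, :, None, :] - carbox[:, None, :, :], axis=-1)
                lig_series = d.reshape(len(idx), -1).min(axis=1)
        out.append(
            DescriptorSeries(
                replica_id=trajectory.replica_id,
                protomer_id=cid,
                frame_index=idx.copy(),
                alpha_c_distance=alpha_c,
                dfg_dihedral=dihedral,
                ke_no_distance=ke,
                ligand_glu501_min_distance=lig_series,
                trim_policy=f"dropped first {start} of {n} frames (trim_fraction={trim_fraction})",
            )
        )
    return out


# ---------------------------------------------------------------------------
# distribution summaries


@dataclass
class HistogramSummary:
    bin_edges: np.ndarray  # n_bins + 1 values
    densities: np.ndarray  # n_bins values, integrates to 1
    n_frames: int

    def __post_init__(self):
        widths = np.diff(self.bin_edges)
        integral = float(np.sum(self.densities * widths))
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(f"histogram densities integrate to {integral}, not 1")

    def mode_center(self) -> float:
        i = int(np.argmax(self.densities))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


def histogram(values, n_bins: int = N_BINS, edges=None) -> HistogramSummary:
    """Density-normalised histogram of pooled descriptor values.

    Pool replicas (and both protomers of a dimer) before calling.  Bin edges
    span [min, max] of the data unless *edges* is supplied.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyDataError("histogram of empty data")
    if edges is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # degenerate single-value input: one unit-width bin row
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, n_bins + 1)
    densities, edges = np.histogram(values, bins=edges, density=True)
    return HistogramSummary(bin_edges=np.asarray(edges), densities=densities, n_frames=values.size)


@dataclass
class ProbabilityEstimate:
    per_replica: list[float]
    mean: float
    sd: float

    def __post_init__(self):
        for p in self.per_replica:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"replica fraction {p} outside [0, 1]")


def state_probability(series_per_replica, predicate) -> ProbabilityEstimate:
    """Fraction of frames satisfying *predicate*, per replica and pooled.

    Parameters
    ----------
    series_per_replica:
        One array of descriptor values per replica (pool both protomers of a
        dimer into one array per replica if desired).
    predicate:
        Vectorised condition mapping a value array to booleans, e.g.
        ``lambda ke: ke <= 4.0`` for salt-bridge occupancy.

    Returns the per-replica fractions, their arithmetic mean, and the sample
    standard deviation across replicas (ddof = 1; 0 for a single replica).
    """
    if not series_per_replica:
        raise EmptyDataError("no replicas supplied")
    fractions = []
    for i, values in enumerate(series_per_replica):
        values = np.asarray(values)
        if values.size == 0:
            raise EmptyDataError(f"replica {i} has zero frames")
        fractions.append(float(np.mean(predicate(values))))
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0
    return ProbabilityEstimate(per_replica=fractions, mean=mean, sd=sd)


@dataclass
class Density2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (nx, ny), integrates to 1
    n_frames: int

    def marginal_x(self) -> HistogramSummary:
        dy = np.diff(self.y_edges)
        densities = (self.density * dy[None, :]).sum(axis=1)
        return HistogramSummary(self.x_edges, densities, self.n_frames)

    def marginal_y(self) -> HistogramSummary:
        dx = np.diff(self.x_edges)
        densities = (self.density * dx[:, None]).sum(axis=0)
        return HistogramSummary(self.y_edges, densities, self.n_frames)

    def mode_center(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return (
            float(0.5 * (self.x_edges[i] + self.x_edges[i + 1])),
            float(0.5 * (self.y_edges[j] + self.y_edges[j + 1])),
        )


def density2d(x, y, n_bins: int = N_BINS, x_edges=None, y_edges=None) -> Density2D:
    """Normalised 2-D density of two paired descriptor series.

    Typical use: αC position against the minimum ligand-donor to Glu501
    carboxylate distance.  The x marginal of the result equals the 1-D
    histogram of *x* when the same edges are used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"paired series differ in length: {x.size} vs {y.size}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise EmptyDataError("2-D density of empty data")

    def make_edges(v, edges):
        if edges is not None:
            return np.asarray(edges, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, n_bins + 1)

    xe = make_edges(x, x_edges)
    ye = make_edges(y, y_edges)
    density, xe, ye = np.histogram2d(x, y, bins=(xe, ye), density=True)
    return Density2D(x_edges=xe, y_edges=ye, density=density, n_frames=x.size)
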