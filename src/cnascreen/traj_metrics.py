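"""Stability read-outs computed on structures and trajectories.

Three metrics decide whether a split tag/catcher system behaves like its
intact parent domain in simulation:

* backbone RMSD of a rigid *core region* against the initial structure,
  after least-squares (Kabsch) superposition on the same selection;
* the 12-6 Lennard-Jones interaction energy between the tag residues and
  the catcher moiety, ``E = sum eps_ij [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6]``
  over all cross pairs, no cutoff;
* the N...O distances of the backbone hydrogen bonds that pair the first
  and last beta-strand, tracked per frame.

Secondary-structure assignment (a Kabsch–Sander-style hydrogen-bond
pattern analysis) and a simple contact fraction for dissociation
monitoring round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ResidueRecord, StructureModel, Trajectory

__all__ = [
    "BACKBONE_ATOMS",
    "CORE_REGIONS",
    "CoreRegion",
    "LJParamTable",
    "HBondPair",
    "MetricSeries",
    "kabsch_superpose",
    "core_rmsd_series",
    "lj_energy",
    "lj_energy_series",
    "infer_exclusions",
    "find_sheet_hbond_pairs",
    "hbond_distance_series",
    "assign_secondary_structure",
    "sheet_content",
    "contact_fraction",
    "backbone_rmsd_between",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class CoreRegion:
    """Rigid-core residue window used as RMSD selection (author numbering)."""

    label: str
    first: int
    last: int
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("core region start exceeds end")


# System-specific core regions comprising the rigid secondary-structure
# elements of the four candidate domains.
CORE_REGIONS: dict[str, CoreRegion] = {
    "3phs": CoreRegion("3phs", 167, 207),
    "4oq1": CoreRegion("4oq1", 183, 223),
    "3kptN": CoreRegion("3kptN", 186, 225),
    "3kptC": CoreRegion("3kptC", 429, 469),
}


@dataclass
class MetricSeries:
    """Per-frame values of one metric with summary statistics."""

    values: np.ndarray
    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        # a constant series (e.g. a frozen trajectory) must average to its
        # value exactly, without summation round-off
        if len(self.values) and np.ptp(self.values) == 0.0:
            return float(self.values[0])
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))  # population SD over frames

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# superposition / RMSD


def kabsch_superpose(ref_coords: np.ndarray, mob_coords: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mob`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mob @ rotation.T + translation`` best fits ``ref`` in the
    least-squares sense; the rotation is proper (det +1).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mob_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _backbone_indices(model: StructureModel, core: CoreRegion,
                      atoms: tuple[str, ...] = BACKBONE_ATOMS) -> list[int]:
    idx: list[int] = []
    missing: list[str] = []
    i = 0
    chain_ids = [core.chain] if core.chain is not None else list(model.chains)
    for cid, residues in model.chains.items():
        for res in residues:
            in_core = (cid in chain_ids) and (core.first <= res.res_seq <= core.last)
            names = {a.name for a in res.atoms}
            if in_core and not set(atoms) <= names:
                missing.append(res.label)
            for a in res.atoms:
                if in_core and a.name in atoms:
                    idx.append(i)
                i += 1
    if missing:
        raise ValueError(f"missing backbone atoms in core residues: {missing}")
    if not idx:
        raise ValueError(f"no residues of core {core.label} ({core.first}-{core.last}) in topology")
    return idx


def core_rmsd_series(traj: Trajectory, core: CoreRegion,
                     atoms: tuple[str, ...] = BACKBONE_ATOMS) -> MetricSeries:
    """Backbone RMSD of the core region versus the initial frame.

    Every frame is superposed on frame 0 using the core backbone
    selection; the RMSD is evaluated over the same atoms.
    """
    idx = _backbone_indices(traj.topology, core, atoms)
    ref = traj.frames[0][idx]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, values[i] = kabsch_superpose(ref, traj.frames[i][idx])
    return MetricSeries(values, unit="A", label=f"core RMSD {core.label}")


def backbone_rmsd_between(a: StructureModel, b: StructureModel,
                          chain_a: str | None = None, chain_b: str | None = None
                          ) -> float:
    """Backbone RMSD between two different domains.

    Residue correspondence is established by a global sequence alignment
    of the two chains (BLOSUM62); aligned residue pairs with complete
    backbones contribute their N, CA, C, O atoms to a Kabsch fit.
    """
    from Bio.Align import PairwiseAligner, substitution_matrices
    from .structure_io import residue_sequence

    res_a = [r for r in a.residues(chain_a) if {n.name for n in r.atoms} >= set(BACKBONE_ATOMS)]
    res_b = [r for r in b.residues(chain_b) if {n.name for n in r.atoms} >= set(BACKBONE_ATOMS)]
    seq_a = residue_sequence(StructureModel(chains={"A": res_a}))
    seq_b = residue_sequence(StructureModel(chains={"A": res_b}))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))
    coords_a = np.array([res_a[i].atom(n).coords for i, _ in pairs for n in BACKBONE_ATOMS])
    coords_b = np.array([res_b[j].atom(n).coords for _, j in pairs for n in BACKBONE_ATOMS])
    _, _, rmsd = kabsch_superpose(coords_a, coords_b)
    return rmsd


# ---------------------------------------------------------------------------
# Lennard-Jones energy

# Minimal per-element 12-6 parameters for protein atoms (AMBER-like
# heavy-atom classes; values in kcal/mol and Angstrom).  Reports must
# name the table used; comparisons in this package are within-toolkit
# (intact domain vs split system), not against absolute published values.
_DEFAULT_LJ_CLASSES: dict[str, tuple[float, float]] = {
    "C": (0.0860, 1.9080),
    "N": (0.1700, 1.8240),
    "O": (0.2100, 1.6612),
    "S": (0.2500, 2.0000),
    "H": (0.0157, 0.6000),
    "SE": (0.2500, 2.0000),
}


@dataclass
class LJParamTable:
    """Per-atom-class epsilon / Rmin/2 with Lorentz-Berthelot-style combining.

    ``eps_ij = sqrt(eps_i eps_j)``; ``Rmin_ij = rmin_half_i + rmin_half_j``.
    """

    classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LJ_CLASSES))
    name: str = "builtin-element-lj"

    def __post_init__(self) -> None:
        for cls, (eps, rmin_half) in self.classes.items():
            if eps < 0 or rmin_half <= 0:
                raise ValueError(f"invalid LJ parameters for class {cls!r}")

    def lookup(self, element: str) -> tuple[float, float]:
        key = element.upper()
        if key not in self.classes:
            raise KeyError(f"no LJ parameters for element {element!r} in table {self.name!r}")
        return self.classes[key]


def lj_energy(coords: np.ndarray, group_a: list[int], group_b: list[int],
              elements: list[str], params: LJParamTable = LJParamTable(),
              exclusions: set[frozenset[int]] | None = None) -> float:
    """12-6 Lennard-Jones energy between two atom groups, kcal/mol.

    ``group_a``/``group_b`` are atom indices into ``coords``; all cross
    pairs count, no cutoff; excluded pairs (e.g. bonded paths across a
    covalent junction) are skipped.  Summation order is deterministic
    (sorted indices) for bit-stable results.
    """
    coords = np.asarray(coords, dtype=float)
    exclusions = exclusions or set()
    eps = np.array([params.lookup(e)[0] for e in elements])
    rmh = np.array([params.lookup(e)[1] for e in elements])
    ia = np.array(sorted(group_a), dtype=int)
    ib = np.array(sorted(group_b), dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    r = cdist(coords[ia], coords[ib])
    shared = np.intersect1d(ia, ib)
    if shared.size:
        raise ValueError(f"groups overlap at atom indices {shared.tolist()}")
    if np.any(r == 0.0):
        raise ValueError("zero interatomic distance in cross pair")
    eps_ij = np.sqrt(np.outer(eps[ia], eps[ib]))
    rmin_ij = np.add.outer(rmh[ia], rmh[ib])
    mask = np.ones_like(r, dtype=bool)
    for pair in exclusions:
        i, j = tuple(pair)
        ai = np.searchsorted(ia, i)
        bj = np.searchsorted(ib, j)
        if ai < len(ia) and ia[ai] == i and bj < len(ib) and ib[bj] == j:
            mask[ai, bj] = False
        ai = np.searchsorted(ia, j)
        bj = np.searchsorted(ib, i)
        if ai < len(ia) and ia[ai] == j and bj < len(ib) and ib[bj] == i:
            mask[ai, bj] = False
    q = (rmin_ij / r) ** 6
    e = eps_ij * (q * q - 2.0 * q)
    return float(np.sum(e[mask]))


def _group_indices(model: StructureModel, chain: str | None,
                   first: int, last: int, heavy_only: bool = False) -> list[int]:
    idx = []
    i = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for a in res.atoms:
                if (chain is None or cid == chain) and first <= res.res_seq <= last:
                    if not (heavy_only and a.element.upper() == "H"):
                        idx.append(i)
                i += 1
    return idx


def infer_exclusions(model: StructureModel, group_a: list[int], group_b: list[int],
                     max_bonds: int = 3, bond_cutoff: float = 1.9
                     ) -> set[frozenset[int]]:
    """Cross-group atom pairs connected by <= ``max_bonds`` covalent bonds.

    Bonds are inferred from heavy-atom distances below ``bond_cutoff``
    (H at 1.2 Å).  In an intact domain this captures the short bonded
    paths across the catcher/tag junction; in a split system there is no
    covalent connection and the result is empty.
    """
    coords = model.coords()
    elements = [a.element.upper() for a in model.atoms()]
    n = len(coords)
    d = cdist(coords, coords)
    cutoff = np.full((n, n), bond_cutoff)
    h = np.array([e == "H" for e in elements])
    cutoff[h, :] = 1.3
    cutoff[:, h] = 1.3
    bonded = (d < cutoff) & (d > 1e-6)
    neighbors = [np.nonzero(bonded[i])[0] for i in range(n)]

    in_b = set(group_b)
    out: set[frozenset[int]] = set()
    for start in group_a:
        # BFS to depth max_bonds
        depth = {start: 0}
        frontier = [start]
        for _ in range(max_bonds):
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    if v not in depth:
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, k in depth.items():
            if v in in_b and 1 <= k <= max_bonds:
                out.add(frozenset((start, v)))
    return out


def lj_energy_series(traj: Trajectory, tag_group: list[int], catcher_group: list[int],
                     params: LJParamTable = LJParamTable(),
                     exclusions: set[frozenset[int]] | None = None) -> MetricSeries:
    """Per-frame tag-catcher Lennard-Jones energy over a trajectory."""
    elements = [a.element for a in traj.topology.atoms()]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        values[i] = lj_energy(traj.frames[i], tag_group, catcher_group,
                              elements, params, exclusions)
    return MetricSeries(values, unit="kcal/mol", label=f"tag-catcher vdW ({params.name})")


# ---------------------------------------------------------------------------
# beta-sheet hydrogen bonds


@dataclass(frozen=True)
class HBondPair:
    donor: tuple[str, int, str]     # residue key of the backbone N
    acceptor: tuple[str, int, str]  # residue key of the backbone O
    reference_distance: float       # Angstrom, N...O in the reference model

    def label(self) -> str:
        d, a = self.donor, self.acceptor
        return f"N({d[0]}{d[1]}{d[2]})...O({a[0]}{a[1]}{a[2]})".replace(" ", "")


def _atoms_in_range(model: StructureModel, chain: str | None, first: int,
                    last: int, name: str) -> list[tuple[ResidueRecord, np.ndarray]]:
    out = []
    for cid, residues in model.chains.items():
        if chain is not None and cid != chain:
            continue
        for res in residues:
            if first <= res.res_seq <= last and res.has_atom(name):
                out.append((res, res.atom(name).coords))
    return out


def find_sheet_hbond_pairs(ref: StructureModel,
                           tag_range: tuple[str | None, int, int],
                           catcher_range: tuple[str | None, int, int],
                           d_max: float = 3.5) -> list[HBondPair]:
    """Backbone N...O pairs bridging the tag and catcher strands.

    Both directions are considered — (tag N, catcher O) and (catcher N,
    tag O) — for all pairs at or below ``d_max`` in the reference
    structure, each atom used at most once per direction (nearest wins).
    """
    pairs: list[HBondPair] = []
    for (dc, df, dl), (ac, af, al) in (((*tag_range,), (*catcher_range,)),
                                       ((*catcher_range,), (*tag_range,))):
        donors = _atoms_in_range(ref, dc, df, dl, "N")
        acceptors = _atoms_in_range(ref, ac, af, al, "O")
        if not donors or not acceptors:
            continue
        d = cdist(np.array([x for _, x in donors]), np.array([x for _, x in acceptors]))
        candidates = sorted(
            ((d[i, j], i, j) for i in range(len(donors)) for j in range(len(acceptors))
             if d[i, j] <= d_max)
        )
        used_d: set[int] = set()
        used_a: set[int] = set()
        for _, i, j in candidates:
            if i in used_d or j in used_a:
                continue
            used_d.add(i)
            used_a.add(j)
            # recompute with the same norm the per-frame series uses, so a
            # frozen trajectory reproduces the reference exactly
            dist = float(np.linalg.norm(donors[i][1] - acceptors[j][1]))
            pairs.append(HBondPair(donor=donors[i][0].key, acceptor=acceptors[j][0].key,
                                   reference_distance=dist))
    pairs.sort(key=lambda p: (p.donor, p.acceptor))
    return pairs


def hbond_distance_series(traj: Trajectory, pairs: list[HBondPair]
                          ) -> dict[str, MetricSeries]:
    """Per-frame N...O distance for each hydrogen-bond pair."""
    res_by_key = {r.key: r for r in traj.topology.residues()}
    # map residue key + atom name -> flat atom index
    index: dict[tuple[tuple[str, int, str], str], int] = {}
    i = 0
    for res in traj.topology.residues():
        for a in res.atoms:
            index[(res.key, a.name)] = i
            i += 1
    out: dict[str, MetricSeries] = {}
    for pair in pairs:
        for key, name in ((pair.donor, "N"), (pair.acceptor, "O")):
            if key not in res_by_key or (key, name) not in index:
                raise KeyError(f"atom {name} of residue {key} not in topology")
        ni = index[(pair.donor, "N")]
        oi = index[(pair.acceptor, "O")]
        d = np.linalg.norm(traj.frames[:, ni, :] - traj.frames[:, oi, :], axis=1)
        out[pair.label()] = MetricSeries(d, unit="A", label=pair.label())
    return out


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander-style)

_KS_COUPLING = 0.084 * 332.0  # q1*q2*f in kcal/mol*A
_KS_CUTOFF = -0.5             # kcal/mol
_CA_NEIGHBOR_MAX = 9.0        # prefilter, A


def _ks_hbonds(model: StructureModel) -> tuple[list[ResidueRecord], set[tuple[int, int]],
                                               list[int]]:
    """Backbone H-bonds: set of (acceptor CO residue, donor NH residue) indices.

    Amide hydrogens are rebuilt from ideal geometry (1.0 Å from N, along
    the preceding residue's C->O direction reversed); proline and chain
    N-termini cannot donate.
    """
    residues: list[ResidueRecord] = []
    chain_of: list[int] = []
    for ci, (cid, chain_res) in enumerate(model.chains.items()):
        for r in chain_res:
            if all(r.has_atom(n) for n in ("N", "CA", "C", "O")):
                residues.append(r)
                chain_of.append(ci)

    n = len(residues)
    ca = np.array([r.atom("CA").coords for r in residues]) if n else np.zeros((0, 3))
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if chain_of[i] != chain_of[i - 1] or residues[i].res_name == "PRO":
            continue
        prev = residues[i - 1]
        if residues[i].res_seq - prev.res_seq not in (0, 1):
            pass  # numbering gap: still treat as chained if consecutive in file
        co = prev.atom("C").coords - prev.atom("O").coords
        norm = np.linalg.norm(co)
        if norm > 1e-6:
            h_pos[i] = residues[i].atom("N").coords + co / norm

    bonds: set[tuple[int, int]] = set()
    if n:
        ca_d = cdist(ca, ca)
    for acc in range(n):
        c = residues[acc].atom("C").coords
        o = residues[acc].atom("O").coords
        for don in range(n):
            if don == acc or h_pos[don] is None:
                continue
            if chain_of[don] == chain_of[acc] and abs(don - acc) < 2:
                continue
            if ca_d[acc, don] > _CA_NEIGHBOR_MAX:
                continue
            nn = residues[don].atom("N").coords
            h = h_pos[don]
            r_on = np.linalg.norm(o - nn)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - nn)
            r_ch = np.linalg.norm(c - h)
            if min(r_on, r_oh, r_cn, r_ch) < 0.5:
                continue  # clashing geometry, not a hydrogen bond
            energy = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _KS_CUTOFF:
                bonds.add((acc, don))
    return residues, bonds, chain_of


def assign_secondary_structure(model: StructureModel) -> dict[tuple[str, int, str], str]:
    """Per-residue secondary structure label: E (strand), H (helix), C (coil).

    Backbone hydrogen bonds are scored with the Kabsch–Sander
    electrostatic energy (bond if E < -0.5 kcal/mol, amide H rebuilt from
    ideal geometry); parallel and antiparallel bridge patterns are
    chained into ladders (bulge-tolerant, index gaps of up to 2) whose
    residues are labelled E, and runs of i,i+4 bonds become H.  Chains
    shorter than 3 residues are all coil.
    """
    residues, bonds, chain_of = _ks_hbonds(model)
    n = len(residues)
    labels = {r.key: "C" for r in model.residues()}
    if n < 3:
        return labels

    def hbond(acc: int, don: int) -> bool:
        return (acc, don) in bonds

    # helices: two consecutive i,i+4 hydrogen bonds
    helix = [False] * n
    for i in range(n - 5):
        if chain_of[i] != chain_of[i + 5]:
            continue
        if hbond(i, i + 4) and hbond(i + 1, i + 5):
            for k in range(i + 1, i + 5):
                helix[k] = True

    # bridges
    def parallel_bridge(i: int, j: int) -> bool:
        a = hbond(j - 1, i) and hbond(i, j + 1) if 0 < j < n - 1 else False
        b = hbond(i - 1, j) and hbond(j, i + 1) if 0 < i < n - 1 else False
        return a or b

    def antiparallel_bridge(i: int, j: int) -> bool:
        a = hbond(i, j) and hbond(j, i)
        b = (hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
             if 0 < i < n - 1 and 0 < j < n - 1 else False)
        return a or b

    bridges: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(n):
            if i == j or (chain_of[i] == chain_of[j] and abs(i - j) < 3):
                continue
            if parallel_bridge(i, j) or antiparallel_bridge(i, j):
                bridges.append((i, j))

    # ladders: merge bridges whose indices differ by <= 2 on both strands
    strand = [False] * n
    unassigned = set(bridges)
    while unassigned:
        seed = unassigned.pop()
        ladder = [seed]
        changed = True
        while changed:
            changed = False
            for br in list(unassigned):
                if any(abs(br[0] - x[0]) <= 2 and abs(br[1] - x[1]) <= 2 for x in ladder):
                    ladder.append(br)
                    unassigned.discard(br)
                    changed = True
        if len(ladder) < 2:
            continue  # isolated bridge: not an extended strand
        for side in (0, 1):
            idxs = sorted(x[side] for x in ladder)
            for k in range(idxs[0], idxs[-1] + 1):
                if chain_of[k] == chain_of[idxs[0]]:
                    strand[k] = True

    for i, res in enumerate(residues):
        if strand[i]:
            labels[res.key] = "E"
        elif helix[i]:
            labels[res.key] = "H"
    return labels


def sheet_content(labels: dict[tuple[str, int, str], str],
                  first: int, last: int, chain: str | None = None) -> float:
    """Percent of residues labelled E within an author-numbered range."""
    if first > last:
        raise ValueError("empty range")
    in_range = {k: v for k, v in labels.items()
                if first <= k[1] <= last and (chain is None or k[0] == chain)}
    if not in_range:
        raise ValueError(f"no residues in range {first}-{last}")
    n_e = sum(1 for v in in_range.values() if v == "E")
    return 100.0 * n_e / len(in_range)


# ---------------------------------------------------------------------------
# contacts


def contact_fraction(traj: Trajectory, group_a: list[int], group_b: list[int],
                     cutoff: float = 4.5) -> float:
    """Fraction of frames with any heavy-atom cross pair within ``cutoff``.

    A proxy for tag dissociation: a bound tag keeps the fraction at 1,
    a departing tag drives it toward the fraction of frames spent bound.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    elements = [a.element.upper() for a in traj.topology.atoms()]
    ia = [i for i in group_a if elements[i] != "H"]
    ib = [i for i in group_b if elements[i] != "H"]
    hits = 0
    for f in range(traj.n_frames):
        d = cdist(traj.frames[f][ia], traj.frames[f][ib])
        if d.min() <= cutoff:
            hits += 1
    return hits / traj.n_frames


def group_indices(model: StructureModel, chain: str | None, first: int, last: int,
                  heavy_only: bool = False) -> list[int]:
    """Flat atom indices of an author-numbered residue range."""
    return _group_indices(model, chain, first, last, heavy_only)
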