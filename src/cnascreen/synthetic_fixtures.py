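"""Seedable synthetic structures and trajectories with known properties.

These fixtures exist to test measurement code, not to simulate physics:
backbone geometry is schematic (flat strands on a regular grid, ideal-ish
bond lengths) but every quantity a metric is supposed to recover —
hydrogen-bond ladder distances, planted triad NZ-CG distances, jitter
magnitudes, drift rates — is exact by construction.  All randomness is
drawn from a single seeded generator recorded in the spec.

The two-strand fixture emulates the parallel pairing of the first and
last β-strand of a CnaB fold: two extended strands, chain ``C``
(catcher) and chain ``T`` (tag), joined by a backbone hydrogen-bond
ladder at a configurable N...O distance.  Acceptor carbonyls are tilted
so that the designated ladder distances come out exactly as declared;
Kabsch–Sander-style assignment still recognizes the strand pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .split_design import SplitSpec
from .structure_io import AtomRecord, ResidueRecord, StructureModel, Trajectory

__all__ = [
    "FixtureSpec",
    "make_two_strand_parallel",
    "plant_triad",
    "make_jitter_trajectory",
    "make_drift_trajectory",
    "make_parent_domain",
    "expected_contact_frames",
    "random_protein_sequence",
]

_RISE = 3.5  # A per residue along a strand


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; ``seed`` fixes all randomness."""

    kind: str = "two_strand_parallel"
    n_residues: int = 8            # per strand
    hbond_distance: float = 2.9    # N...O, A
    triad_nz_cg: float = 1.33      # A
    sigma: float = 0.5             # per-coordinate jitter, A
    n_frames: int = 100
    drift_vector: tuple[float, float, float] = (0.0, -0.5, 0.0)  # A/frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _residue(chain: str, num: int, name: str,
             atoms: list[tuple[str, str, np.ndarray]]) -> ResidueRecord:
    return ResidueRecord(chain, num, name,
                         [AtomRecord(0, n, el, xyz) for n, el, xyz in atoms])


def _strand_residue_atoms(k: int, d: float, t: float, n_res: int,
                          mirror: bool) -> list[tuple[str, str, np.ndarray]]:
    """Backbone atoms of residue k of one strand (see module docstring).

    ``mirror=False`` builds the catcher strand in the y=0 plane with
    donors/acceptors pointing toward -y; ``mirror=True`` builds the tag
    strand at y=-t pointing toward +y.  Even residues are the bridge
    residues: their amide H (rebuilt by the assignment code from the
    preceding carbonyl) points across the gap and their own carbonyl
    accepts from the partner strand.
    """
    s = _RISE
    x0 = s * k
    sign = 1.0 if not mirror else -1.0
    y0 = 0.0 if not mirror else -t
    xoff = 0.0 if not mirror else -2.3

    n = np.array([x0 + xoff, y0, 0.0])
    ca = np.array([x0 + xoff + 1.2, y0 + 0.9 * sign, 0.4 * (-1.0) ** k])
    c = np.array([x0 + xoff + 2.3, y0 + 0.2 * sign, 0.0])
    if k % 2 == 1:
        # carbonyl points away from the partner strand: orients the next
        # residue's amide H toward it
        o = c + np.array([0.0, 1.23 * sign, 0.0])
    else:
        if not mirror:
            # catcher acceptor: O sits exactly above the tag donor N of
            # residue k+2 (tilted carbonyl; exact ladder distance); the
            # last bridge residue has no partner and points away instead
            o = np.array([s * (k + 2) - 2.3, -(t) + d, 0.0]) if k + 2 < n_res else \
                c + np.array([0.0, 1.23, 0.0])
        else:
            # tag acceptor: O sits exactly below the catcher donor N of
            # residue k (vertical carbonyl of length 1.23)
            o = np.array([s * k, -d, 0.0])
    return [("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)]


def make_two_strand_parallel(spec: FixtureSpec = FixtureSpec()) -> StructureModel:
    """Two parallel extended strands joined by an exact H-bond ladder.

    Chain ``C`` (residues 1..n) is the catcher strand, chain ``T``
    (residues 101..100+n) the tag strand; designated ladder pairs
    (catcher N_k, tag O_k) and (tag N_{k+2}, catcher O_k) for even k sit
    at exactly ``spec.hbond_distance``.
    """
    if spec.n_residues < 4:
        raise ValueError("need at least 4 residues per strand")
    if spec.hbond_distance < 2.0:
        raise ValueError("hbond_distance below 2 A is geometrically impossible")
    d = spec.hbond_distance
    t = d + 1.03  # strand-plane separation giving exact vertical ladder rungs
    model = StructureModel(header_id=f"synthetic-two-strand(seed={spec.seed})")
    model.chains["C"] = [
        _residue("C", k + 1, "GLY", _strand_residue_atoms(k, d, t, spec.n_residues, False))
        for k in range(spec.n_residues)
    ]
    model.chains["T"] = [
        _residue("T", k + 101, "GLY", _strand_residue_atoms(k, d, t, spec.n_residues, True))
        for k in range(spec.n_residues)
    ]
    return model


def _append_atoms(res: ResidueRecord, atoms: list[tuple[str, str, np.ndarray]]) -> None:
    for name, el, xyz in atoms:
        res.atoms.append(AtomRecord(0, name, el, xyz))


def _build_lys_side_chain(res: ResidueRecord, nz: np.ndarray) -> None:
    ca = res.atom("CA").coords
    for frac, name in ((0.2, "CB"), (0.4, "CG"), (0.6, "CD"), (0.8, "CE")):
        res.atoms.append(AtomRecord(0, name, "C", ca + frac * (nz - ca)))
    res.atoms.append(AtomRecord(0, "NZ", "N", nz))


def plant_triad(model: StructureModel, spec: FixtureSpec,
                lys_index: int = 2, asn_index: int = 3,
                glu_index: int = 4) -> StructureModel:
    """Plant a Lys/Asn/Glu active site across the two strands.

    The Lys goes on the catcher strand, the Asn on the tag strand with
    NZ-CG equal to ``spec.triad_nz_cg`` exactly, and the Glu carboxylate
    carbon within catalytic range of NZ.  Indices are 0-based positions
    within each strand.
    """
    out = model.copy()
    catcher = out.chains["C"]
    tag = out.chains["T"]
    for idx, pool, what in ((lys_index, catcher, "lys"), (glu_index, catcher, "glu"),
                            (asn_index, tag, "asn")):
        if not 0 <= idx < len(pool):
            raise ValueError(f"{what}_index {idx} outside strand of {len(pool)} residues")
    if lys_index == glu_index:
        raise ValueError("lys and glu cannot share a residue")

    asn = tag[asn_index]
    asn.res_name = "ASN"
    ca_asn = asn.atom("CA").coords
    lys = catcher[lys_index]
    lys.res_name = "LYS"
    ca_lys = lys.atom("CA").coords

    toward_lys = ca_lys - ca_asn
    toward_lys = toward_lys / np.linalg.norm(toward_lys)
    cg = ca_asn + 2.4 * toward_lys
    _append_atoms(asn, [
        ("CB", "C", ca_asn + 1.2 * toward_lys),
        ("CG", "C", cg),
        ("OD1", "O", cg + np.array([1.0, 0.5, 0.3])),
        ("ND2", "N", cg + np.array([-1.0, 0.5, 0.3])),
    ])

    u = ca_lys - cg
    u = u / np.linalg.norm(u)
    nz = cg + spec.triad_nz_cg * u  # exact NZ-CG distance by construction
    _build_lys_side_chain(lys, nz)

    glu = catcher[glu_index]
    glu.res_name = "GLU"
    ca_glu = glu.atom("CA").coords
    cd = nz + 3.5 * np.array([0.0, 0.28, 0.96]) / 1.0
    _append_atoms(glu, [
        ("CB", "C", ca_glu + 0.33 * (cd - ca_glu)),
        ("CG", "C", ca_glu + 0.66 * (cd - ca_glu)),
        ("CD", "C", cd),
        ("OE1", "O", cd + np.array([0.9, 0.8, 0.0])),
        ("OE2", "O", cd + np.array([-0.9, 0.8, 0.0])),
    ])
    return out


def make_jitter_trajectory(model: StructureModel, spec: FixtureSpec) -> Trajectory:
    """``n_frames`` copies of the model with i.i.d. Gaussian displacement.

    Frame 0 is the unperturbed model; frames 1.. add N(0, sigma) per
    coordinate.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base = model.coords()
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.sigma > 0 and spec.n_frames > 1:
        frames[1:] += rng.normal(0.0, spec.sigma, size=frames[1:].shape)
    return Trajectory(topology=model.copy(), frames=frames)


def make_drift_trajectory(model: StructureModel, spec: FixtureSpec,
                          drift_chain: str = "T") -> Trajectory:
    """Trajectory in which one chain drifts away linearly (plus jitter).

    The ``drift_chain`` (default: the tag) is translated by
    ``i * drift_vector`` in frame i, emulating tag dissociation; the
    remaining atoms only jitter.  Frame 0 is unperturbed.
    """
    v = np.asarray(spec.drift_vector, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("drift_vector must be non-zero")
    rng = np.random.default_rng(spec.seed)
    base = model.coords()
    mask = np.zeros(len(base), dtype=bool)
    i = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for _ in res.atoms:
                mask[i] = cid == drift_chain
                i += 1
    if not mask.any():
        raise ValueError(f"no atoms in drift chain {drift_chain!r}")
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for f in range(1, spec.n_frames):
        frames[f, mask] += f * v
        if spec.sigma > 0:
            frames[f] += rng.normal(0.0, spec.sigma, size=frames[f].shape)
    return Trajectory(topology=model.copy(), frames=frames)


def expected_contact_frames(model: StructureModel, spec: FixtureSpec,
                            drift_chain: str = "T", cutoff: float = 4.5) -> int:
    """Frames a jitter-free drift fixture stays in contact, by construction.

    Pure arithmetic over the initial coordinates: the drifted chain is
    displaced by ``f * drift_vector`` in frame f, so the frame-f distance
    of a cross pair with initial separation ``D`` is ``|D + f v|``.
    """
    v = np.asarray(spec.drift_vector, dtype=float)
    static, moving = [], []
    for cid, residues in model.chains.items():
        for res in residues:
            for a in res.atoms:
                if a.element.upper() == "H":
                    continue
                (moving if cid == drift_chain else static).append(a.coords)
    diffs = np.asarray(moving)[:, None, :] - np.asarray(static)[None, :, :]
    count = 0
    for f in range(spec.n_frames):
        d = np.linalg.norm(diffs + f * v, axis=-1)
        if d.min() <= cutoff:
            count += 1
    return count


# Average amino-acid background frequencies (Robinson & Robinson style),
# used to draw composition-realistic synthetic sequences.
_AA_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}


def random_protein_sequence(n: int, seed: int) -> str:
    """A synthetic amino-acid sequence drawn from background frequencies.

    Serves as a composition-realistic stand-in where only length and
    average properties of a protein segment matter (e.g. construct-mass
    estimates); deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = list(_AA_BACKGROUND)
    probs = np.array(list(_AA_BACKGROUND.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


# ---------------------------------------------------------------------------
# synthetic parent domain


def make_parent_domain(split: SplitSpec,
                       lys: int | None = None,
                       acceptor: int | None = None,
                       catalytic: int | None = None,
                       triad_nz_cg: float = 1.33,
                       header_id: str = "") -> StructureModel:
    """Synthetic stand-in for a deposited parent domain (author numbering).

    Builds a single chain spanning the split's domain range as a
    hairpin — the first half runs out along +x, the second half returns
    along -x — so that a residue late in the chain (the acceptor, in the
    tag range) lies spatially close to an early one (the reactive Lys, in
    the catcher range), as in a real CnaB fold.  The triad side chains
    are planted with NZ-CG exactly ``triad_nz_cg`` and the catalytic
    carboxylate within range; side-chain geometry is otherwise schematic.

    Default triad positions (used when a system's active site is not
    given): Lys at catcher_first+9, Glu at catcher_first+19, Asn at
    tag_first+4.
    """
    first, last = split.domain_range
    m = last - first + 1
    lys = lys if lys is not None else split.catcher_first + 9
    catalytic = catalytic if catalytic is not None else split.catcher_first + 19
    acceptor = acceptor if acceptor is not None else split.tag_first + 4
    for num, name, lo, hi in ((lys, "lys", split.catcher_first, split.catcher_last),
                              (catalytic, "catalytic", split.catcher_first, split.catcher_last),
                              (acceptor, "acceptor", split.tag_first, split.tag_last)):
        if not lo <= num <= hi:
            raise ValueError(f"{name} position {num} outside its range {lo}-{hi}")

    half = m // 2
    chain_id = split.chain
    residues: list[ResidueRecord] = []
    for i in range(m):
        if i < half:
            x, y = _RISE * i, 0.0
        else:
            x, y = _RISE * (m - 1 - i), -6.5
        atoms = [
            ("N", "N", np.array([x, y, 0.0])),
            ("CA", "C", np.array([x + 1.2, y + 0.9, 0.4 * (-1.0) ** i])),
            ("C", "C", np.array([x + 2.3, y + 0.2, 0.0])),
            ("O", "O", np.array([x + 2.3, y + 0.2 + (1.23 if i % 2 else -1.23), 0.0])),
        ]
        residues.append(_residue(chain_id, first + i, "GLY", atoms))
    model = StructureModel(header_id=header_id or f"synthetic-parent-{split.chain}")
    model.chains[chain_id] = residues

    by_num = {r.res_seq: r for r in residues}
    asn = by_num[acceptor]
    asn.res_name = "ASN"
    lys_res = by_num[lys]
    lys_res.res_name = "LYS"
    ca_asn = asn.atom("CA").coords
    ca_lys = lys_res.atom("CA").coords
    toward = ca_lys - ca_asn
    toward = toward / np.linalg.norm(toward)
    # CG and NZ straddle the inter-strand midpoint at the exact planted
    # distance, keeping both side chains clear of the partner backbone
    mid = 0.5 * (ca_asn + ca_lys)
    cg = mid - 0.5 * triad_nz_cg * toward
    nz = mid + 0.5 * triad_nz_cg * toward
    _append_atoms(asn, [
        ("CB", "C", ca_asn + 0.5 * (cg - ca_asn)),
        ("CG", "C", cg),
        ("OD1", "O", cg + np.array([0.5, 0.5, 1.0])),
        ("ND2", "N", cg + np.array([-0.5, 0.5, 1.0])),
    ])
    _build_lys_side_chain(lys_res, nz)

    glu = by_num[catalytic]
    glu.res_name = "GLU"
    ca_glu = glu.atom("CA").coords
    # the catalytic carboxylate is placed near NZ directly; in this
    # schematic fold the Glu backbone may be distant, so the side chain
    # is stretched (metrology stand-in, not physical geometry)
    cd = nz + 3.5 * np.array([0.0, 0.28, 0.96])
    _append_atoms(glu, [
        ("CB", "C", ca_glu + 0.33 * (cd - ca_glu)),
        ("CG", "C", ca_glu + 0.66 * (cd - ca_glu)),
        ("CD", "C", cd),
        ("OE1", "O", cd + np.array([0.9, 0.8, 0.0])),
        ("OE2", "O", cd + np.array([-0.9, 0.8, 0.0])),
    ])
    return model
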