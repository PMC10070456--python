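"""Idealized cellulose microfibril builders.

Constructs N-chain cellulose Iβ-like microfibrils as stacks of glucan-chain
layers (e.g. the 18-chain ``"234432"`` habit: one integer per layer, each
integer the number of chains in that layer), with optional water molecules
placed inside the fibril (between cellulose sheets) and/or as a surface
monolayer.  The atomic detail is an idealized 21-atom anhydroglucose template
(C6H10O5) repeated along the chain axis with the 2-fold screw flip; it is
parameterized so that the lattice periodicities that control wide-angle
diffraction peak positions -- the inter-sheet (200) spacing and the mean
diagonal (110)/(1-10) spacing -- are exact by construction.

Coordinate convention: the sheet-stacking axis (the (200) direction) is *y*,
the chain axis is *z*, and chains within a sheet are spread along *x*.
Adjacent sheets are offset by half the intra-sheet chain spacing laterally
and by half a residue rise along the chain axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeParams",
    "MicrofibrilModel",
    "PlacementError",
    "ModelIOError",
    "build_fibril",
    "add_water",
    "model_preset",
    "write_model",
    "read_model",
    "ATOMS_PER_RESIDUE",
]

#: atoms per anhydroglucose residue (C6 H10 O5)
ATOMS_PER_RESIDUE = 21

_KNOWN_ELEMENTS = {"H", "C", "N", "O"}


class PlacementError(RuntimeError):
    """Raised when the requested water count cannot be placed.

    Carries ``achieved`` -- the number of waters that were placed before
    the bounded retry budget ran out.
    """

    def __init__(self, requested: int, achieved: int, where: str):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} {where} waters "
            f"under the minimum-distance constraints"
        )


class ModelIOError(ValueError):
    """Malformed coordinate file."""


@dataclass(frozen=True)
class LatticeParams:
    """Lattice periodicities of the idealized fibril (all in Angstrom).

    d200 : inter-sheet spacing (distance between glucan-chain layers).
    d110_mean : mean of the two diagonal inter-chain plane spacings; with
        the symmetric half-spacing sheet offset used here the two diagonal
        families are degenerate, so both equal this value exactly.
    chain_rise : translation per anhydroglucose along the chain axis
        (half the ~10.38 A cellobiose repeat).
    """

    d200: float = 4.0
    d110_mean: float = 5.57
    chain_rise: float = 5.19

    def __post_init__(self):
        for name in ("d200", "d110_mean", "chain_rise"):
            if not getattr(self, name) > 0:
                raise ValueError(f"LatticeParams.{name} must be > 0")
        if self.d110_mean <= self.d200 / 2:
            raise ValueError("d110_mean too small for this d200 (no real lateral spacing)")

    @property
    def lateral_spacing(self) -> float:
        """Intra-sheet chain spacing *a* giving the requested diagonal spacing.

        For sheets spaced s = d200 with an a/2 lateral offset between
        adjacent sheets, both diagonal plane families have spacing
        a*s / sqrt(a^2/4 + s^2); solving for *a* gives the value below.
        """
        d, s = self.d110_mean, self.d200
        return d * s / math.sqrt(s * s - d * d / 4.0)


# Idealized anhydroglucose template: 21 atoms (6 C, 5 O, 10 H), ring roughly
# in the x-z plane so the ribbon is thin along the stacking axis y.  Bond
# lengths are plausible (~1.4-1.5 A C-C/C-O, ~1.0 A X-H); fine geometry is
# not meant to be crystallographic, only adequate for pair-distance
# statistics at wide angles.
_TEMPLATE = [
    # ring: C1 C2 C3 C4 C5 O5 at hexagon vertices, slight chair pucker in y
    ("C", 0.000, 0.25, -1.450),   # C1
    ("C", 1.256, -0.25, -0.725),  # C2
    ("C", 1.256, 0.25, 0.725),    # C3
    ("C", 0.000, -0.25, 1.450),   # C4
    ("C", -1.256, 0.25, 0.725),   # C5
    ("O", -1.256, -0.25, -0.725), # O5 (ring oxygen)
    # substituents
    ("O", 2.450, 0.30, -1.420),   # O2 hydroxyl on C2
    ("O", 2.450, -0.30, 1.420),   # O3 hydroxyl on C3
    ("O", 0.000, -0.15, 2.870),   # O4 glycosidic bridge toward next residue
    ("C", -2.530, -0.25, 1.480),  # C6 exocyclic
    ("O", -3.650, 0.30, 0.840),   # O6 hydroxyl on C6
    # hydrogens
    ("H", 0.000, 1.33, -1.500),   # H1
    ("H", 1.300, -1.33, -0.760),  # H2
    ("H", 1.300, 1.33, 0.760),    # H3
    ("H", 0.000, -1.33, 1.500),   # H4
    ("H", -1.300, 1.33, 0.760),   # H5
    ("H", -2.540, -1.30, 1.760),  # H61
    ("H", -2.650, 0.33, 2.390),   # H62
    ("H", 3.270, -0.15, -1.050),  # HO2
    ("H", 3.270, 0.15, 1.050),    # HO3
    ("H", -4.450, -0.15, 1.190),  # HO6
]

_WATER_GEOMETRY = np.array(
    [
        [0.0, 0.0, 0.0],            # O
        [0.9572, 0.0, 0.0],         # H
        [-0.2400, 0.9266, 0.0],     # H (104.5 deg HOH angle)
    ]
)


@dataclass
class MicrofibrilModel:
    """Atoms of an N-chain cellulose fibril with optional waters.

    Parallel arrays: ``elements`` (str), ``coords`` (N,3) A, ``chain_ids``
    (str; cellulose chains 'A'.., interior waters 'I', monolayer waters 'W'),
    ``residue_index`` (int, per chain).
    """

    arrangement: str
    residues_per_chain: int
    elements: np.ndarray
    coords: np.ndarray
    chain_ids: np.ndarray
    residue_index: np.ndarray
    lattice: LatticeParams = field(default_factory=LatticeParams)

    @property
    def n_chains(self) -> int:
        return sum(int(c) for c in self.arrangement)

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.chain_ids, ("I", "W"))

    @property
    def waters_inside(self) -> int:
        return int(np.sum((self.chain_ids == "I") & (self.elements == "O")))

    @property
    def waters_monolayer(self) -> int:
        return int(np.sum((self.chain_ids == "W") & (self.elements == "O")))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atoms(self):
        """Iterate (element, x, y, z, chain_id, residue_index) tuples."""
        for el, (x, y, z), cid, ri in zip(
            self.elements, self.coords, self.chain_ids, self.residue_index
        ):
            yield (el, float(x), float(y), float(z), str(cid), int(ri))

    def layer_planes(self) -> np.ndarray:
        """y coordinates of the chain-layer planes, bottom to top."""
        n_layers = len(self.arrangement)
        return (np.arange(n_layers) - (n_layers - 1) / 2.0) * self.lattice.d200


def _parse_arrangement(arrangement: str) -> list[int]:
    if not arrangement:
        raise ValueError("arrangement must be a non-empty digit string")
    if not arrangement.isdigit():
        raise ValueError(f"arrangement must contain only digits, got {arrangement!r}")
    digits = [int(c) for c in arrangement]
    if any(d < 1 for d in digits):
        raise ValueError("every layer must contain at least one chain")
    return digits


def build_fibril(
    arrangement: str,
    residues_per_chain: int,
    lattice: LatticeParams | None = None,
) -> MicrofibrilModel:
    """Build an idealized fibril with the given chains-per-layer arrangement.

    Layers are stacked along y with spacing ``lattice.d200`` exactly; chains
    within a layer sit at multiples of the lateral spacing *a*, with
    alternate layers offset by a/2 in x and half a residue rise in z.  Each
    chain is the 21-atom anhydroglucose template repeated with an
    alternate-residue 180-degree flip about the chain axis.  The model is
    centered at the origin.
    """
    digits = _parse_arrangement(arrangement)
    if residues_per_chain < 1:
        raise ValueError("residues_per_chain must be >= 1")
    lattice = lattice or LatticeParams()
    a = lattice.lateral_spacing
    rise = lattice.chain_rise
    n_layers = len(digits)

    tmpl = np.array([[x, y, z] for _, x, y, z in _TEMPLATE])
    tmpl_el = [el for el, *_ in _TEMPLATE]
    flipped = tmpl * np.array([-1.0, -1.0, 1.0])  # 2-fold screw about z

    elements, coords, chain_ids, residx = [], [], [], []
    chain_letters = "ABCDEFGHJKLMNPQRSTUVXYZabcdefghjklmnpqrstuvxyz"
    chain_no = 0
    for layer, n_chains in enumerate(digits):
        y0 = (layer - (n_layers - 1) / 2.0) * lattice.d200
        x_off = (layer % 2) * a / 2.0
        z_off = (layer % 2) * rise / 2.0
        for k in range(n_chains):
            x0 = (k - (n_chains - 1) / 2.0) * a + x_off
            cid = chain_letters[chain_no % len(chain_letters)]
            for r in range(residues_per_chain):
                base = tmpl if r % 2 == 0 else flipped
                xyz = base + np.array([x0, y0, z_off + r * rise])
                coords.append(xyz)
                elements.extend(tmpl_el)
                chain_ids.extend([cid] * ATOMS_PER_RESIDUE)
                residx.extend([r + 1] * ATOMS_PER_RESIDUE)
            chain_no += 1

    coords = np.concatenate(coords, axis=0)
    # center at origin without disturbing the layer-plane spacing pattern:
    # subtract the mean chain-axis/lateral position; y is symmetric already
    coords -= coords.mean(axis=0) * np.array([1.0, 0.0, 1.0])
    return MicrofibrilModel(
        arrangement=arrangement,
        residues_per_chain=residues_per_chain,
        elements=np.array(elements),
        coords=coords,
        chain_ids=np.array(chain_ids),
        residue_index=np.array(residx),
        lattice=lattice,
    )


def _min_dist(point: np.ndarray, others: np.ndarray) -> float:
    if len(others) == 0:
        return np.inf
    return float(np.sqrt(np.min(np.sum((others - point) ** 2, axis=1))))


def _make_waters(o_positions: list[np.ndarray], rng: np.random.Generator):
    """Expand water oxygen sites into O+2H atoms with fixed geometry."""
    els, xyz = [], []
    for o in o_positions:
        # random rotation about z for variety, deterministic under rng
        ang = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        w = _WATER_GEOMETRY @ rot.T + o
        els.extend(["O", "H", "H"])
        xyz.append(w)
    return els, (np.concatenate(xyz, axis=0) if xyz else np.zeros((0, 3)))


def add_water(
    model: MicrofibrilModel,
    mode: str = "both",
    n_inside: int = 0,
    n_monolayer: int = 0,
    shell: float = 3.0,
    seed: int = 0,
    min_oo: float = 2.4,
    min_fibril: float = 1.5,
    max_tries_per_water: int = 2000,
) -> MicrofibrilModel:
    """Return a copy of *model* with waters added by seeded rejection sampling.

    ``mode`` selects which counts apply ('inside', 'monolayer' or 'both').
    Interior waters sit on the mid-planes between adjacent cellulose sheets
    (stacking coordinate strictly between two layer planes), sampled on a
    jittered grid; monolayer waters lie within ``shell`` A of some fibril
    atom.  Water oxygens keep at least ``min_oo`` A from each other and
    ``min_fibril`` A (monolayer: ``min_oo``) from fibril heavy atoms.
    """
    if mode not in ("inside", "monolayer", "both"):
        raise ValueError(f"unknown water mode {mode!r}")
    if n_inside < 0 or n_monolayer < 0:
        raise ValueError("water counts must be >= 0")
    if shell <= 0:
        raise ValueError("shell must be > 0")
    want_inside = n_inside if mode in ("inside", "both") else 0
    want_mono = n_monolayer if mode in ("monolayer", "both") else 0
    if want_inside == 0 and want_mono == 0:
        return replace(model)

    rng = np.random.default_rng(seed)
    heavy = model.coords[model.elements != "H"]
    placed_o: list[np.ndarray] = []

    if want_inside:
        planes = model.layer_planes()
        fib_x = model.coords[:, 0]
        fib_z = model.coords[:, 2]
        galleries = [(planes[i] + planes[i + 1]) / 2.0 for i in range(len(planes) - 1)]
        if not galleries:
            raise PlacementError(want_inside, 0, "interior")
        xlo, xhi = fib_x.min() + 1.0, fib_x.max() - 1.0
        zlo, zhi = fib_z.min() + 1.0, fib_z.max() - 1.0
        # jittered-grid candidate sites per gallery, visited round-robin
        step = max(min_oo, 2.4)
        xs = np.arange(xlo, xhi + 1e-9, step)
        zs = np.arange(zlo, zhi + 1e-9, step)
        sites = [
            [np.array([x, ymid, z]) for x in xs for z in zs] for ymid in galleries
        ]
        for s in sites:
            rng.shuffle(s)
        count, tries = 0, 0
        budget = want_inside * max_tries_per_water
        ptr = [0] * len(galleries)
        g = 0
        while count < want_inside and tries < budget:
            tries += 1
            gi = g % len(galleries)
            g += 1
            if ptr[gi] >= len(sites[gi]):
                # refill with fresh jitter
                rng.shuffle(sites[gi])
                ptr[gi] = 0
            cand = sites[gi][ptr[gi]] + rng.uniform(-0.8, 0.8, 3) * np.array([1, 0, 1])
            ptr[gi] += 1
            if _min_dist(cand, heavy) < min_fibril:
                continue
            if placed_o and _min_dist(cand, np.array(placed_o)) < min_oo:
                continue
            placed_o.append(cand)
            count += 1
        if count < want_inside:
            raise PlacementError(want_inside, count, "interior")
        inside_slice = slice(0, count)
    else:
        inside_slice = slice(0, 0)

    if want_mono:
        # First hydration shell: waters sit at H-bond distance from surface
        # oxygens, offset outward, so the layer stays in lateral registry
        # with the surface lattice (candidates generated from an interior
        # oxygen fall too close to neighboring chains and are rejected).
        offset = min(2.8, shell - 0.05)
        if offset < min_oo:
            raise ValueError("shell too small for the hydration-shell offset")
        oxy = model.coords[model.elements == "O"]
        zlim = model.coords[:, 2].min(), model.coords[:, 2].max()
        cands = []
        for o in oxy:
            radial = np.linalg.norm(o[:2])
            if radial > 1e-6:
                u = np.array([o[0] / radial, o[1] / radial, 0.0])
                cands.append(o + u * offset)
            for sgn, lim in ((1.0, zlim[1]), (-1.0, zlim[0])):
                if abs(o[2] - lim) < 3.0:
                    cands.append(o + np.array([0.0, 0.0, sgn * offset]))
        cands = [c for c in cands if _min_dist(c, heavy) >= min_oo]
        start = len(placed_o)
        count = 0
        for i in rng.permutation(len(cands)):
            cand = cands[i]
            if placed_o and _min_dist(cand, np.array(placed_o)) < min_oo:
                continue
            placed_o.append(cand)
            count += 1
            if count == want_mono:
                break
        if count < want_mono:
            raise PlacementError(want_mono, count, "monolayer")
        mono_slice = slice(start, start + count)
    else:
        mono_slice = slice(len(placed_o), len(placed_o))

    els_i, xyz_i = _make_waters(placed_o[inside_slice], rng)
    els_m, xyz_m = _make_waters(placed_o[mono_slice], rng)
    n_i, n_m = len(els_i), len(els_m)
    return MicrofibrilModel(
        arrangement=model.arrangement,
        residues_per_chain=model.residues_per_chain,
        elements=np.concatenate([model.elements, els_i, els_m]),
        coords=np.concatenate([model.coords, xyz_i, xyz_m], axis=0),
        chain_ids=np.concatenate(
            [model.chain_ids, np.full(n_i, "I"), np.full(n_m, "W")]
        ),
        residue_index=np.concatenate(
            [
                model.residue_index,
                np.repeat(np.arange(1, n_i // 3 + 1), 3),
                np.repeat(np.arange(1, n_m // 3 + 1), 3),
            ]
        ),
        lattice=model.lattice,
    )


def model_preset(number: int, seed: int = 0) -> MicrofibrilModel:
    """The four 18-chain (234432, 4 residues/chain = 72 glucose) presets.

    1: dry fibril; 2: + 102 monolayer waters; 3: + 36 interior waters;
    4: + 36 interior and 108 monolayer waters.
    """
    base = build_fibril("234432", 4)
    if number == 1:
        return base
    if number == 2:
        return add_water(base, "monolayer", n_monolayer=102, seed=seed)
    if number == 3:
        return add_water(base, "inside", n_inside=36, seed=seed)
    if number == 4:
        return add_water(base, "both", n_inside=36, n_monolayer=108, seed=seed)
    raise ValueError(f"unknown model preset {number}; expected 1-4")


def write_model(model: MicrofibrilModel, path) -> None:
    """Write the model as a PDB file (ATOM for cellulose, HETATM/HOH waters)."""
    import gemmi

    if model.n_atoms == 0:
        raise ValueError("refusing to write a model with no atoms")
    st = gemmi.Structure()
    st.name = f"fibril_{model.arrangement}"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    counters: dict[str, int] = {}
    for el, x, y, z, cid, ri in model.atoms:
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        ch = chains[cid]
        is_water = cid in ("I", "W")
        resname = "HOH" if is_water else "GLC"
        key = f"{cid}:{ri}"
        if key not in counters:
            counters[key] = 0
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(ri, " ")
            res.het_flag = "H" if is_water else "A"
            ch.add_residue(res)
        res = ch[-1]
        counters[key] += 1
        at = gemmi.Atom()
        at.name = f"{el}{counters[key]}"
        at.element = gemmi.Element(el)
        at.pos = gemmi.Position(x, y, z)
        res.add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def read_model(path) -> MicrofibrilModel:
    """Read a PDB coordinate file written by :func:`write_model`.

    Validates element symbols line-by-line first so malformed records are
    reported with their line number.
    """
    import gemmi

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                el = line[76:78].strip() or line[12:14].strip().rstrip("0123456789")
                if el.upper() not in _KNOWN_ELEMENTS:
                    raise ModelIOError(
                        f"{path}:{lineno}: unknown element symbol {el!r}"
                    )
                for col, name in ((30, "x"), (38, "y"), (46, "z")):
                    try:
                        float(line[col : col + 8])
                    except ValueError:
                        raise ModelIOError(
                            f"{path}:{lineno}: unparseable {name} coordinate"
                        ) from None
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelIOError(f"{path}: {exc}") from exc
    elements, coords, chain_ids, residx = [], [], [], []
    cellulose_chains = set()
    res_per_chain: dict[str, int] = {}
    for md in st:
        for ch in md:
            for res in ch:
                for at in res:
                    elements.append(at.element.name)
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
                    chain_ids.append(ch.name)
                    residx.append(res.seqid.num)
                if res.name != "HOH":
                    cellulose_chains.add(ch.name)
                    res_per_chain[ch.name] = max(
                        res_per_chain.get(ch.name, 0), res.seqid.num
                    )
        break  # first model only
    if not elements:
        raise ModelIOError(f"{path}: no atoms found")
    n_chains = len(cellulose_chains)
    rpc = max(res_per_chain.values()) if res_per_chain else 0
    return MicrofibrilModel(
        arrangement=str(n_chains) if n_chains else "0",
        residues_per_chain=rpc,
        elements=np.array(elements),
        coords=np.array(coords),
        chain_ids=np.array(chain_ids),
        residue_index=np.array(residx),
    )
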