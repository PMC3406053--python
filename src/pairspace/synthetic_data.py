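"""Synthetic corpora and synthetic tensors with known statistical structure.

The corpus generator emulates the properties of a culled experimental chain
set that matter to the pair pipeline: chain lengths from 40 up to ~1000
residues, realistic amino-acid composition, secondary-structure segments
(helix/strand/turn/coil), per-residue relative solvent accessibility with a
buried/exposed mixture, and per-residue functional-atom coordinates hanging
off a compact self-avoiding Cα trace.  Helix segments follow ideal alpha-helix
geometry (2.3 Å radius, 1.5 Å rise, 100 deg per residue), strands are
extended zigzags, and coil/turn steps are a correlated 3.8 Å random walk with
a weak pull toward the centroid so chains stay globular and sequence-distant
residues come into contact.

Hydrophobic types (Ala, Ile, Leu, Val, Phe, Met) are enriched in helix and
strand segments and preferentially buried, giving the corpus a hydrophobic
core whose pair statistics concentrate, as in real proteins, on those types.

`generate_powerlaw_tensor` draws cell populations i.i.d. from a discrete
power law P(R) proportional to R^-lambda, scattered over random distinct 8-D
indices — the generative target for the rank-frequency fitting machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .pair_tensor import BinScheme, DEFAULT_SCHEME, DIM_NAMES, SparseCountTensor
from .residues import AA3, AA3_TO_1, FUNCTIONAL_ATOMS, SS_CATEGORIES
from .structure_io import ResidueRecord, ValidatedChain

#: background amino-acid frequencies (order = AA3), a standard database profile
NATURAL_COMPOSITION = np.array([
    0.078, 0.051, 0.045, 0.054, 0.019, 0.043, 0.063, 0.073, 0.022, 0.053,
    0.091, 0.059, 0.022, 0.039, 0.052, 0.068, 0.059, 0.014, 0.032, 0.066,
])
NATURAL_COMPOSITION = NATURAL_COMPOSITION / NATURAL_COMPOSITION.sum()

HYDROPHOBIC = ("ALA", "ILE", "LEU", "VAL", "PHE", "MET")

#: approximate Cα -> functional-atom distance per type (Å)
FUNCTIONAL_OFFSET = {
    "ALA": 1.5, "ARG": 6.7, "ASN": 2.5, "ASP": 2.5, "CYS": 2.8,
    "GLN": 3.8, "GLU": 3.7, "GLY": 0.0, "HIS": 3.1, "ILE": 2.5,
    "LEU": 2.6, "LYS": 6.4, "MET": 4.0, "PHE": 5.0, "PRO": 2.3,
    "SER": 2.4, "THR": 2.4, "TRP": 4.5, "TYR": 6.5, "VAL": 2.5,
}

_SS_TO_CODE = {"helix": "H", "strand": "E", "turn": "T", "coil": "C"}

_CA_MIN_SEPARATION = 3.0     # self-avoidance exclusion radius (Å)
_CA_STEP = 3.8               # Cα-Cα virtual bond (Å)


@dataclass
class CorpusParams:
    """Parameters of the synthetic corpus generator.  `seed` is mandatory."""

    seed: int
    n_chains: int = 50
    min_length: int = 40
    max_length: int = 300
    composition: np.ndarray = field(default_factory=lambda: NATURAL_COMPOSITION.copy())
    ss_weights: dict = field(default_factory=lambda: {
        "helix": 0.32, "strand": 0.22, "turn": 0.12, "coil": 0.34})
    ss_mean_lengths: dict = field(default_factory=lambda: {
        "helix": 10.0, "strand": 5.0, "turn": 3.0, "coil": 6.0})
    hydrophobic_boost: float = 2.0       # composition multiplier in helix/strand
    buried_frac_hydrophobic: float = 0.75
    buried_frac_polar: float = 0.30

    def __post_init__(self):
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or (comp < 0).any() or comp.sum() <= 0:
            raise ValueError("composition must be 20 non-negative frequencies")
        self.composition = comp / comp.sum()
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid length range")
        if self.n_chains < 0:
            raise ValueError("n_chains must be >= 0")


@dataclass
class PowerLawParams:
    """Parameters of the synthetic power-law tensor generator."""

    lambda_: float
    n_cells: int
    r_max: int
    seed: int

    def __post_init__(self):
        if self.lambda_ <= 1:
            raise ValueError("lambda must be > 1")
        if self.n_cells < 100:
            raise ValueError("n_cells must be >= 100")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")


@dataclass
class SyntheticChain:
    chain: ValidatedChain
    pdb_text: str
    annotation_text: str


# ---------------------------------------------------------------------------
# Secondary-structure segments and composition
# ---------------------------------------------------------------------------

def _sample_ss_labels(rng: np.random.Generator, length: int, params: CorpusParams) -> list[str]:
    cats = list(params.ss_weights)
    weights = np.array([params.ss_weights[c] for c in cats], dtype=float)
    weights /= weights.sum()
    labels: list[str] = []
    prev = None
    while len(labels) < length:
        cat = cats[rng.choice(len(cats), p=weights)]
        if cat == prev:                      # avoid trivially merged segments
            continue
        mean = max(params.ss_mean_lengths[cat], 1.0)
        seg = 1 + rng.geometric(1.0 / mean)
        labels.extend([cat] * min(seg, length - len(labels)))
        prev = cat
    return labels


def _sample_aa(rng: np.random.Generator, ss: str, params: CorpusParams) -> str:
    weights = params.composition.copy()
    if ss in ("helix", "strand") and params.hydrophobic_boost != 1.0:
        for aa in HYDROPHOBIC:
            weights[AA3.index(aa)] *= params.hydrophobic_boost
        weights /= weights.sum()
    return AA3[rng.choice(20, p=weights)]


def _sample_sa(rng: np.random.Generator, aa: str, params: CorpusParams) -> float:
    p_buried = (params.buried_frac_hydrophobic if aa in HYDROPHOBIC
                else params.buried_frac_polar)
    if rng.random() < p_buried:
        if rng.random() < 0.05:
            return 0.0                       # fully buried: SA<=0 bin
        return float(rng.uniform(0.5, 10.0))
    if rng.random() < 0.03:
        return float(rng.uniform(100.5, 120.0))   # SA>100 bin
    return float(rng.uniform(10.5, 100.0))


# ---------------------------------------------------------------------------
# Cα walk
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _orthonormal_frame(rng: np.random.Generator, axis: np.ndarray):
    e1 = _random_unit(rng)
    e1 -= axis * (e1 @ axis)
    n = np.linalg.norm(e1)
    if n < 1e-8:
        return _orthonormal_frame(rng, axis)
    e1 /= n
    e2 = np.cross(axis, e1)
    return e1, e2


def _segment_axis(rng: np.random.Generator, positions: list[np.ndarray],
                  r_target: float) -> np.ndarray:
    """New segment direction, biased inward once the walk leaves the globule."""
    prev = positions[-1]
    centroid = np.mean(positions, axis=0)
    v = rng.standard_normal(3)
    off = prev - centroid
    dist = np.linalg.norm(off)
    if dist > r_target:
        v -= 1.5 * off / dist
    return v / np.linalg.norm(v)


def _walk_ca(rng: np.random.Generator, ss_labels: list[str],
             max_chain_restarts: int = 25) -> np.ndarray:
    """Self-avoiding Cα trace following the secondary-structure segments."""
    n = len(ss_labels)
    r_target = 3.3 * n ** (1 / 3) + 2.0

    for _ in range(max_chain_restarts):
        positions = [np.zeros(3)]
        state: dict | None = None
        failed = False
        for i in range(1, n):
            placed = False
            for attempt in range(40):
                if state is None or state["ss"] != ss_labels[i] or attempt > 0:
                    state = _new_segment_state(rng, ss_labels[i], positions, r_target)
                candidate = _next_position(state, positions)
                prior = np.asarray(positions[:-1]) if len(positions) > 1 else None
                ok = True
                if prior is not None and len(prior):
                    d2 = ((prior - candidate) ** 2).sum(axis=1)
                    ok = bool(d2.min() >= _CA_MIN_SEPARATION ** 2)
                if ok:
                    positions.append(candidate)
                    state["k"] += 1
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.asarray(positions)
    raise RuntimeError(
        f"could not place a self-avoiding chain of {n} residues "
        f"after {max_chain_restarts} restarts")


def _new_segment_state(rng, ss, positions, r_target) -> dict:
    axis = _segment_axis(rng, positions, r_target)
    state = {"ss": ss, "k": 1, "axis": axis, "anchor": positions[-1]}
    if ss == "helix":
        e1, e2 = _orthonormal_frame(rng, axis)
        phase = rng.uniform(0, 2 * math.pi)
        # base chosen so that k=0 lands on the anchor residue
        base = positions[-1] - 2.3 * (math.cos(phase) * e1 + math.sin(phase) * e2)
        state.update(e1=e1, e2=e2, phase=phase, base=base,
                     rise=1.5, radius=2.3, turn=math.radians(100.0))
    elif ss == "strand":
        e1, _ = _orthonormal_frame(rng, axis)
        state.update(perp=e1, rise=3.3, amp=0.95)
    else:
        state.update(step=_CA_STEP, persistence=0.5)
    return state


def _next_position(state: dict, positions: list[np.ndarray]) -> np.ndarray:
    k = state["k"]
    if state["ss"] == "helix":
        ang = state["phase"] + k * state["turn"]
        return (state["base"] + state["axis"] * state["rise"] * k
                + state["radius"] * (math.cos(ang) * state["e1"]
                                     + math.sin(ang) * state["e2"]))
    if state["ss"] == "strand":
        return (state["anchor"] + state["axis"] * state["rise"] * k
                + state["perp"] * state["amp"] * ((-1) ** k))
    # coil / turn: correlated step from the last position
    prev = positions[-1]
    if len(positions) > 1:
        prev_dir = prev - positions[-2]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
    else:
        prev_dir = state["axis"]
    direction = state["persistence"] * prev_dir + state["axis"]
    direction /= np.linalg.norm(direction)
    return prev + direction * state["step"]


# ---------------------------------------------------------------------------
# Chain assembly and file rendering
# ---------------------------------------------------------------------------

def _place_functional_atoms(rng: np.random.Generator, aa: str,
                            ca: np.ndarray) -> np.ndarray:
    names = FUNCTIONAL_ATOMS[aa]
    if names == ("CA",):
        return ca[None, :].copy()
    offset = FUNCTIONAL_OFFSET[aa]
    d1 = _random_unit(rng)
    atoms = [ca + offset * d1]
    if len(names) == 2:
        # second atom ~65 degrees away from the first, same radius
        perp = _random_unit(rng)
        perp -= d1 * (perp @ d1)
        perp /= np.linalg.norm(perp)
        d2 = math.cos(math.radians(65)) * d1 + math.sin(math.radians(65)) * perp
        atoms.append(ca + offset * d2)
    return np.asarray(atoms)


def generate_chain(params: CorpusParams, chain_seed: int | np.random.SeedSequence,
                   structure_id: str = "S000", chain_id: str = "A",
                   length: int | None = None) -> SyntheticChain:
    """Generate one synthetic chain plus its PDB and annotation renderings.

    Deterministic given (params, chain_seed).  The emitted files re-ingest
    through `structure_io` into an identical validated chain (coordinates to
    PDB fixed-width precision).
    """
    rng = np.random.default_rng(chain_seed)
    if length is None:
        length = int(rng.integers(params.min_length, params.max_length + 1))
    ss_labels = _sample_ss_labels(rng, length, params)
    ca = _walk_ca(rng, ss_labels)
    # round to PDB precision so in-memory and re-ingested coordinates agree
    ca = np.round(ca, 3)

    residues: list[ResidueRecord] = []
    for i in range(length):
        aa = _sample_aa(rng, ss_labels[i], params)
        sa = _sample_sa(rng, aa, params)
        functional = np.round(_place_functional_atoms(rng, aa, ca[i]), 3)
        residues.append(ResidueRecord(
            aa=aa,
            chain_id=chain_id,
            seq_index=i + 1,
            ca_xyz=ca[i],
            functional_xyz=functional,
            ss=ss_labels[i],
            sa=sa,
            provenance=(structure_id, str(i + 1), chain_id),
        ))
    chain = ValidatedChain(structure_id, chain_id, residues)
    return SyntheticChain(
        chain=chain,
        pdb_text=chain_to_pdb(chain),
        annotation_text=chain_to_annotation_tsv(chain),
    )


def chain_to_pdb(chain: ValidatedChain) -> str:
    """Render a validated chain as PDB-format text (via gemmi)."""
    st = gemmi.Structure()
    st.name = chain.structure_id
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain.chain_id)
    for rec in chain.residues:
        res = gemmi.Residue()
        res.name = rec.aa
        res.seqid = gemmi.SeqId(rec.seq_index, " ")
        res.het_flag = "A"    # force ATOM records even for 1-residue chains
        names = ["CA"]
        coords = [rec.ca_xyz]
        for atom_name, xyz in zip(FUNCTIONAL_ATOMS[rec.aa], rec.functional_xyz):
            if atom_name != "CA":
                names.append(atom_name)
                coords.append(xyz)
        for atom_name, xyz in zip(names, coords):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.element = gemmi.Element(atom_name[0])
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    for entity in st.entities:
        entity.entity_type = gemmi.EntityType.Polymer
        entity.polymer_type = gemmi.PolymerType.PeptideL
    for res in st[0][chain.chain_id]:
        res.het_flag = "A"
    return st.make_pdb_string()


def chain_to_annotation_tsv(chain: ValidatedChain) -> str:
    """Render per-residue annotations in the TSV dialect."""
    lines = ["structure_id\tchain_id\tseq_number\tinsertion_code\taa_1letter\tss_code\tsa_percent"]
    for rec in chain.residues:
        lines.append("\t".join([
            chain.structure_id, chain.chain_id, str(rec.seq_index), "_",
            AA3_TO_1[rec.aa], _SS_TO_CODE[rec.ss], repr(rec.sa),
        ]))
    return "\n".join(lines) + "\n"


def generate_corpus(
    params: CorpusParams,
    out_dir: str | Path | None = None,
) -> list[SyntheticChain]:
    """Generate `params.n_chains` chains; optionally write PDB/annotation
    files plus a manifest TSV to `out_dir`."""
    master = np.random.SeedSequence(params.seed)
    seeds = master.spawn(params.n_chains)
    chains: list[SyntheticChain] = []
    for i, seed in enumerate(seeds):
        sid = f"S{i:03d}"
        chains.append(generate_chain(params, seed, structure_id=sid))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_lines = ["structure_id\tpdb\tannotations"]
        for syn in chains:
            sid = syn.chain.structure_id
            (out / f"{sid}.pdb").write_text(syn.pdb_text)
            (out / f"{sid}.tsv").write_text(syn.annotation_text)
            manifest_lines.append(f"{sid}\t{sid}.pdb\t{sid}.tsv")
        (out / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return chains


# ---------------------------------------------------------------------------
# Synthetic power-law tensors
# ---------------------------------------------------------------------------

def generate_powerlaw_tensor(
    params: PowerLawParams,
    scheme: BinScheme = DEFAULT_SCHEME,
) -> SparseCountTensor:
    """Scatter n_cells populations drawn from P(R) ~ R^-lambda over random
    distinct 8-D indices."""
    rng = np.random.default_rng(params.seed)
    shape = scheme.shape
    space = int(np.prod(shape))
    if params.n_cells > space:
        raise ValueError(
            f"n_cells={params.n_cells} exceeds the index space of {space} cells")

    r = np.arange(1, params.r_max + 1, dtype=float)
    pmf = r ** (-params.lambda_)
    pmf /= pmf.sum()
    populations = rng.choice(np.arange(1, params.r_max + 1), size=params.n_cells, p=pmf)

    linear = np.unique(rng.integers(0, space, size=int(params.n_cells * 1.1) + 16))
    while linear.size < params.n_cells:
        extra = rng.integers(0, space, size=params.n_cells)
        linear = np.unique(np.concatenate([linear, extra]))
    linear = rng.permutation(linear)[:params.n_cells]
    idx_arrays = np.unravel_index(linear, shape)

    tensor = SparseCountTensor(shape, DIM_NAMES, meta={
        "mode": "synthetic", "lambda": repr(params.lambda_),
        "r_max": str(params.r_max), "seed": str(params.seed)})
    for row in range(params.n_cells):
        idx = tuple(int(a[row]) for a in idx_arrays)
        tensor.add(idx, float(populations[row]))
    return tensor
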