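"""Coordinate parsing and the flat scattering-site representation.

Reads PDB/mmCIF files (via gemmi), resolves alternate locations, optionally
expands deposited biological-assembly transforms, merges hydrogens into
their parent heavy-atom groups, and assigns each remaining heavy atom a
scattering-site type (group label) from the form-factor table.  The result,
a :class:`StructureModel`, is a structure-of-arrays container consumed by
all scattering/PDDF engines.

Coordinates are in Å throughout; momentum transfer q = 4π·sinθ/λ in Å⁻¹.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .formfactors import AtomGroupTable, DEFAULT_SOLVENT_ED, UnknownGroupError
from .residues import is_known_residue, lookup_group_label

__all__ = [
    "AtomRecord", "StructureModel", "Selection", "StructureError",
    "read_structure", "assign_atom_types", "effective_electrons",
    "max_pair_distance", "write_pdb", "write_sites_tsv", "read_sites_tsv",
    "parse_selection", "molecular_weight",
]

logger = logging.getLogger("solscat")

_HYDROGEN = ("H", "D")


class StructureError(ValueError):
    """Unreadable file, missing model/assembly, or empty atom selection."""


@dataclass(frozen=True)
class AtomRecord:
    """One scattering site (heavy atom + implicit hydrogens)."""

    group_label: str
    position: tuple[float, float, float]
    z_electrons: float
    volume: float
    type_index: int
    chain: str
    res_name: str
    res_seq: int
    atom_name: str
    element: str


@dataclass
class StructureModel:
    """Flat list of scattering sites with a compact type registry.

    ``type_labels`` is the registry of distinct group labels present (its
    length is the number of scattering types N_T); ``type_index`` maps each
    atom into it.  Electron counts and displaced volumes come from the
    form-factor table and include implicit hydrogens.
    """

    positions: np.ndarray                  # (N, 3) Å
    group_labels: np.ndarray               # (N,) str
    type_index: np.ndarray                 # (N,) int32
    type_labels: list[str]
    chain_ids: np.ndarray
    res_names: np.ndarray
    res_seqs: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    solvent_ed: float = DEFAULT_SOLVENT_ED
    source: dict = field(default_factory=dict)
    table: AtomGroupTable = field(default_factory=AtomGroupTable.default,
                                  repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructureError("positions must have shape (N, 3)")
        if self.n_atoms == 0:
            raise StructureError("structure has no scattering sites")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates")

    # -- basic properties -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    @property
    def z_electrons(self) -> np.ndarray:
        z_by_type = np.array([self.table[t].z for t in self.type_labels])
        return z_by_type[self.type_index]

    @property
    def volumes(self) -> np.ndarray:
        v_by_type = np.array([self.table[t].volume for t in self.type_labels])
        return v_by_type[self.type_index]

    @property
    def delta_z(self) -> np.ndarray:
        """Effective electron numbers ΔZ_j = Z_j − ρ_s·V_j."""
        return self.z_electrons - self.solvent_ed * self.volumes

    def record(self, i: int) -> AtomRecord:
        return AtomRecord(
            group_label=str(self.group_labels[i]),
            position=tuple(self.positions[i]),
            z_electrons=float(self.z_electrons[i]),
            volume=float(self.volumes[i]),
            type_index=int(self.type_index[i]),
            chain=str(self.chain_ids[i]),
            res_name=str(self.res_names[i]),
            res_seq=int(self.res_seqs[i]),
            atom_name=str(self.atom_names[i]),
            element=str(self.elements[i]),
        )

    def __iter__(self):
        return (self.record(i) for i in range(self.n_atoms))

    # -- derived models ---------------------------------------------------

    def subset(self, mask: np.ndarray, name: str | None = None) -> "StructureModel":
        """Sub-model keeping the parent's type registry (and indices)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.shape != (self.n_atoms,):
                raise StructureError("boolean mask has wrong length")
            idx = np.nonzero(mask)[0]
        else:
            idx = mask.astype(np.intp)
        if idx.size == 0:
            raise StructureError(f"empty selection{f' {name!r}' if name else ''}")
        src = dict(self.source)
        if name:
            src["selection"] = name
        return replace(self, positions=self.positions[idx],
                       group_labels=self.group_labels[idx],
                       type_index=self.type_index[idx],
                       chain_ids=self.chain_ids[idx],
                       res_names=self.res_names[idx],
                       res_seqs=self.res_seqs[idx],
                       atom_names=self.atom_names[idx],
                       elements=self.elements[idx],
                       source=src)

    def with_solvent_ed(self, solvent_ed: float) -> "StructureModel":
        if solvent_ed < 0:
            raise ValueError("solvent electron density must be non-negative")
        return replace(self, solvent_ed=solvent_ed)


# --------------------------------------------------------------- selection

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class Selection:
    """Named atom selection (the subunit unit of PDDF decomposition).

    Built either from a mini-language string -- space-joined clauses of
    ``chain A`` / ``chains A,B`` / ``resname BCD`` / ``resi 1-12,20`` --
    or from an explicit index set.
    """

    name: str
    chains: tuple[str, ...] | None = None
    res_names: tuple[str, ...] | None = None
    res_ranges: tuple[tuple[int, int], ...] | None = None
    indices: tuple[int, ...] | None = None

    def mask(self, model: StructureModel) -> np.ndarray:
        m = np.ones(model.n_atoms, dtype=bool)
        if self.indices is not None:
            m = np.zeros(model.n_atoms, dtype=bool)
            m[list(self.indices)] = True
            return m
        if self.chains is not None:
            m &= np.isin(model.chain_ids, self.chains)
        if self.res_names is not None:
            m &= np.isin(model.res_names, self.res_names)
        if self.res_ranges is not None:
            rm = np.zeros(model.n_atoms, dtype=bool)
            for lo, hi in self.res_ranges:
                rm |= (model.res_seqs >= lo) & (model.res_seqs <= hi)
            m &= rm
        return m

    def apply(self, model: StructureModel) -> StructureModel:
        return model.subset(self.mask(model), name=self.name)


def parse_selection(text: str, name: str | None = None) -> Selection:
    """Parse the selection mini-language (see :class:`Selection`)."""
    tokens = text.split()
    chains: list[str] = []
    res_names: list[str] = []
    ranges: list[tuple[int, int]] = []
    indices: list[int] = []
    i = 0
    while i < len(tokens):
        key = tokens[i].lower()
        if key == "and":
            i += 1
            continue
        if i + 1 >= len(tokens):
            raise StructureError(f"selection clause {key!r} missing argument")
        arg = tokens[i + 1]
        if key in ("chain", "chains"):
            chains.extend(a for a in arg.split(",") if a)
        elif key == "resname":
            res_names.extend(a.upper() for a in arg.split(",") if a)
        elif key in ("resi", "resid"):
            for part in arg.split(","):
                m = _RANGE_RE.match(part)
                if not m:
                    raise StructureError(f"bad residue range: {part!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                ranges.append((lo, hi))
        elif key == "index":
            indices.extend(int(a) for a in arg.split(",") if a)
        elif key == "indexfile":
            indices.extend(int(line) for line in Path(arg).read_text().split())
        else:
            raise StructureError(f"unknown selection keyword: {key!r}")
        i += 2
    return Selection(name=name or text,
                     chains=tuple(chains) or None,
                     res_names=tuple(res_names) or None,
                     res_ranges=tuple(ranges) or None,
                     indices=tuple(indices) or None)


# ----------------------------------------------------------------- reading

def _pick_altlocs(residue) -> list:
    """Resolve alternate locations: highest occupancy, ties to first in file.

    Only atoms carrying an altloc letter compete; blank-altloc atoms are
    kept as-is (repeated names without altlocs are distinct sites).
    """
    out, best = [], {}
    for atom in residue:
        if not atom.altloc or atom.altloc == "\0":
            out.append(atom)
        else:
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ + 1e-9:
                best[atom.name] = atom
    return out + [a for a in best.values()
                  if not any(o.name == a.name for o in out)]


_H_LABELS = {("C", 1): "CH", ("C", 2): "CH2", ("C", 3): "CH3",
             ("N", 1): "NH", ("N", 2): "NH2", ("N", 3): "NH3",
             ("O", 1): "OH", ("O", 2): "H2O", ("S", 1): "SH"}

_warned_unknown: set[tuple[str, str]] = set()


def _residue_sites(chain_name, residue, table: AtomGroupTable):
    """Yield (label, atom, element) for the heavy atoms of one residue.

    Explicit hydrogens are merged into the nearest heavy atom of the same
    residue when the residue is not in the topology dictionaries; for known
    residues the dictionary's implicit-hydrogen labels already account for
    them and explicit H atoms are simply absorbed.
    """
    atoms = _pick_altlocs(residue)
    heavies = [a for a in atoms if a.element.name not in _HYDROGEN]
    hydros = [a for a in atoms if a.element.name in _HYDROGEN]
    known = is_known_residue(residue.name)

    h_counts = [0] * len(heavies)
    if hydros and not known and heavies:
        hp = np.array([[h.pos.x, h.pos.y, h.pos.z] for h in hydros])
        pp = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in heavies])
        d2 = ((hp[:, None, :] - pp[None, :, :]) ** 2).sum(axis=2)
        for row in d2:
            j = int(np.argmin(row))
            if row[j] < 1.6 ** 2:
                h_counts[j] += 1

    for a, nh in zip(heavies, h_counts):
        el = a.element.name.upper()
        label = lookup_group_label(residue.name, a.name)
        if label is None:
            name = a.name.strip().upper()
            if (not known and name in table
                    and table[name].element.upper() == el):
                # fixture/site-list convention: atom name is the group label
                label = name
            else:
                label = _H_LABELS.get((el, nh), el if nh == 0 else el)
            if label not in table:
                label = el
            if label not in table:
                raise UnknownGroupError(el)
            key = (residue.name, a.name)
            if not known and key not in _warned_unknown:
                _warned_unknown.add(key)
                logger.warning("unknown residue atom %s/%s typed as %r",
                               residue.name, a.name, label)
        yield label, a


def read_structure(path, model: int = 1, assembly: str | int | None = None,
                   include_het: bool = False, include_waters: bool = False,
                   selection: str | Selection | None = None,
                   solvent_ed: float = DEFAULT_SOLVENT_ED,
                   table: AtomGroupTable | None = None) -> StructureModel:
    """Read a PDB/mmCIF file into a typed scattering-site list.

    Parameters
    ----------
    model : 1-based model number (NMR ensembles; default first model).
    assembly : name/index of a deposited biological assembly (BIOMT /
        assembly operators) to expand; None keeps the asymmetric unit.
    include_het : keep non-polymer heteroatoms (ligands); waters are
        controlled separately by ``include_waters``.
    selection : selection string or :class:`Selection` applied at the end.
    """
    table = table or AtomGroupTable.default()
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    if model < 1 or model > len(st):
        raise StructureError(
            f"model {model} not in {path.name} (has {len(st)} model(s))")
    gmodel = st[model - 1]

    if assembly is not None:
        asm = None
        for i, a in enumerate(st.assemblies):
            if str(assembly) == a.name or (isinstance(assembly, int) and i == assembly - 1):
                asm = a
                break
        if asm is None:
            raise StructureError(
                f"assembly {assembly!r} not found in {path.name} "
                f"(available: {[a.name for a in st.assemblies]})")
        gmodel = gemmi.make_assembly(asm, gmodel, gemmi.HowToNameCopiedChain.AddNumber)

    rows = []
    for chain in gmodel:
        for residue in chain:
            if residue.is_water():
                if not include_waters:
                    continue
            elif residue.het_flag == "H" and not include_het:
                continue
            for label, a in _residue_sites(chain.name, residue, table):
                rows.append((label, a.pos.x, a.pos.y, a.pos.z, chain.name,
                             residue.name, residue.seqid.num, a.name,
                             a.element.name.upper()))
    if not rows:
        raise StructureError(f"no scattering sites left after filters in {path.name}")

    m = _model_from_rows(rows, solvent_ed, table,
                         source={"file": str(path), "model": model,
                                 "assembly": assembly})
    if selection is not None:
        sel = parse_selection(selection) if isinstance(selection, str) else selection
        m = sel.apply(m)
    return assign_atom_types(m)


def _model_from_rows(rows, solvent_ed, table, source) -> StructureModel:
    labels = np.array([r[0] for r in rows])
    pos = np.array([[r[1], r[2], r[3]] for r in rows], dtype=np.float64)
    return StructureModel(
        positions=pos,
        group_labels=labels,
        type_index=np.zeros(len(rows), dtype=np.int32),
        type_labels=[],
        chain_ids=np.array([r[4] for r in rows]),
        res_names=np.array([r[5] for r in rows]),
        res_seqs=np.array([r[6] for r in rows], dtype=np.int64),
        atom_names=np.array([r[7] for r in rows]),
        elements=np.array([r[8] for r in rows]),
        solvent_ed=solvent_ed,
        source=source,
        table=table,
    )


def assign_atom_types(model: StructureModel) -> StructureModel:
    """(Re)build the compact type registry from the group labels.

    Deterministic and order-independent: the registry is sorted
    alphabetically.  Raises :class:`UnknownGroupError` listing offending
    atoms if a label is missing from the table.
    """
    bad = [str(l) for l in np.unique(model.group_labels) if l not in model.table]
    if bad:
        raise UnknownGroupError(", ".join(bad))
    type_labels = sorted(str(l) for l in np.unique(model.group_labels))
    index_of = {l: i for i, l in enumerate(type_labels)}
    tidx = np.array([index_of[str(l)] for l in model.group_labels], dtype=np.int32)
    return replace(model, type_labels=type_labels, type_index=tidx)


def effective_electrons(model: StructureModel) -> np.ndarray:
    """Per-atom effective electron numbers ΔZ_j = Z_j − ρ_s·V_j."""
    return model.delta_z


# ------------------------------------------------------------ max distance

def _max_dist_brute(pos: np.ndarray, block: int = 2048) -> float:
    best = 0.0
    n = pos.shape[0]
    for i0 in range(0, n, block):
        a = pos[i0:i0 + block]
        for j0 in range(i0, n, block):
            b = pos[j0:j0 + block]
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
            best = max(best, float(d2.max()))
    return np.sqrt(best)


def max_pair_distance(model_or_positions) -> float:
    """Exact largest pair distance (Dmax) over all scattering sites.

    Uses the convex hull for large point sets (the diameter is attained at
    hull vertices), with a blocked O(N²) scan otherwise or as fallback;
    both are exact.
    """
    pos = (model_or_positions.positions
           if isinstance(model_or_positions, StructureModel)
           else np.asarray(model_or_positions, dtype=float))
    if pos.shape[0] < 2:
        raise StructureError("need at least two atoms for a pair distance")
    if pos.shape[0] > 3000:
        try:
            from scipy.spatial import ConvexHull
            hull = ConvexHull(pos)
            pos = pos[hull.vertices]
        except Exception:  # degenerate geometry; fall back to full scan
            pass
    return _max_dist_brute(pos)


def molecular_weight(model: StructureModel) -> float:
    """Molecular weight in kDa, implicit hydrogens included."""
    mass = 0.0
    for label in model.type_labels:
        entry = model.table[label]
        per = gemmi.Element(entry.element).weight + entry.n_h * 1.008
        mass += per * int(np.sum(model.type_index == model.type_labels.index(label)))
    return mass / 1000.0


# ----------------------------------------------------------------- writers

def write_pdb(model: StructureModel, path) -> None:
    """Write sites as a minimal PDB file (fixtures, debugging)."""
    lines = []
    for i in range(model.n_atoms):
        x, y, z = model.positions[i]
        name = str(model.atom_names[i])[:4]
        lines.append(
            "ATOM  {serial:5d} {name:<4s}{res:>4s} {chain:1s}{seq:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                serial=(i + 1) % 100000, name=name,
                res=str(model.res_names[i])[:3], chain=str(model.chain_ids[i])[:1],
                seq=int(model.res_seqs[i]) % 10000, x=x, y=y, z=z, occ=1.0, b=0.0,
                el=str(model.elements[i])[:2]))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_TSV_HEADER = "# solscat sites v1: label x y z chain resname resseq atomname element"


def write_sites_tsv(model: StructureModel, path) -> None:
    """Dump the internal site list as TSV (round-trips exactly)."""
    out = [_TSV_HEADER, f"# solvent_ed {model.solvent_ed!r}"]
    for i in range(model.n_atoms):
        x, y, z = model.positions[i]
        out.append("\t".join([
            str(model.group_labels[i]), repr(float(x)), repr(float(y)),
            repr(float(z)), str(model.chain_ids[i]), str(model.res_names[i]),
            str(int(model.res_seqs[i])), str(model.atom_names[i]),
            str(model.elements[i])]))
    Path(path).write_text("\n".join(out) + "\n")


def read_sites_tsv(path, solvent_ed: float | None = None,
                   table: AtomGroupTable | None = None) -> StructureModel:
    """Read a site-list TSV written by :func:`write_sites_tsv`.

    Also accepts the compact 4-column form (label, x, y, z) used for
    bundled/derived coordinate sets.
    """
    table = table or AtomGroupTable.default()
    rows = []
    sed = DEFAULT_SOLVENT_ED
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "solvent_ed" in line:
                sed = float(line.split()[-1])
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) == 4:
            label, x, y, z = f
            chain, resn, seq, aname, el = "A", "UNK", 1, label, table[label].element
        else:
            label, x, y, z, chain, resn, seq, aname, el = f[:9]
        rows.append((label, float(x), float(y), float(z), chain, resn,
                     int(seq), aname, el))
    if solvent_ed is not None:
        sed = solvent_ed
    m = _model_from_rows(rows, sed, table, source={"file": str(path)})
    return assign_atom_types(m)
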