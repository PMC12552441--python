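"""Structure records, pairing and curation of phosphosite comparison groups.

A comparison group pairs structures of one protein (same UniProt accession)
in which the same residue(s) carry a phosphate in one set of structures and
not in the other.  Phosphoresidues are recognised by their PDB chemical
component codes (SEP, TPO, PTR, HIP, NEP); HIP and NEP are both treated as
phosphohistidine.  Curation applies the standard quality filters: X-ray/EM
structures must satisfy resolution and R-free bounds, every structure must
cover a minimum fraction of the reference sequence and be consistent with
the other structures of the group (median pairwise sequence similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

#: phosphoresidue component code -> canonical parent residue
PHOSPHO_PARENT = {
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HIP": "HIS",
    "NEP": "HIS",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ResidueRecord:
    """One residue: author numbering, parent residue code, atom coordinates.

    ``aa3`` always holds the canonical parent residue (SER for SEP etc.);
    the phosphorylation state is carried separately in ``phospho_code``.
    """

    author_index: int
    aa3: str
    atoms: Dict[str, np.ndarray]
    phospho_code: str = "none"

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.aa3, "X")

    @property
    def is_phospho(self) -> bool:
        return self.phospho_code != "none"

    def atom(self, name: str) -> Optional[np.ndarray]:
        return self.atoms.get(name)


@dataclass
class StructureRecord:
    """One polypeptide chain, possibly with several models (NMR)."""

    structure_id: str
    uniprot_id: Optional[str]
    models: List[List[ResidueRecord]]
    method: Optional[str] = None        # "xray" | "em" | "nmr"
    resolution: Optional[float] = None  # Å
    r_free: Optional[float] = None
    last_author: Optional[str] = None

    @property
    def residues(self) -> List[ResidueRecord]:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def phospho_sites(self) -> frozenset:
        return frozenset(r.author_index for r in self.residues if r.is_phospho)

    def ca_coords(self, indices: Optional[Sequence[int]] = None,
                  model: int = 0) -> np.ndarray:
        """Cα coordinates, optionally restricted to 0-based residue positions."""
        residues = self.models[model]
        if indices is None:
            indices = range(len(residues))
        return np.array([residues[i].atoms["CA"] for i in indices])


@dataclass
class ResidueMap:
    """Matched residue positions (0-based) between two structures."""

    pairs: List[Tuple[int, int]]
    identity: float
    similarity: float

    def reversed(self) -> "ResidueMap":
        return ResidueMap([(j, i) for i, j in self.pairs],
                          self.identity, self.similarity)


@dataclass
class PhosphositeGroup:
    """One protein + one (possibly multisite) phosphorylation event."""

    uniprot_id: str
    site_indices: frozenset
    phospho_structures: List[StructureRecord] = field(default_factory=list)
    nonphospho_structures: List[StructureRecord] = field(default_factory=list)

    @property
    def is_multisite(self) -> bool:
        return len(self.site_indices) > 1

    @property
    def structures(self) -> List[StructureRecord]:
        return list(self.phospho_structures) + list(self.nonphospho_structures)


# ---------------------------------------------------------------------------
# parsing

_METHOD_MAP = {
    "X-RAY DIFFRACTION": "xray",
    "ELECTRON MICROSCOPY": "em",
    "SOLUTION NMR": "nmr",
    "SOLID-STATE NMR": "nmr",
}


def _scan_pdb_header(path: Path):
    """Pull method, R-free and raw AUTHOR text from PDB header records.

    gemmi surfaces resolution and author names but not EXPDTA/R-free for
    minimal headers, so those records are read directly.
    """
    method = None
    r_free = None
    authors = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM", "MODEL"):
                break
            if rec == "EXPDTA":
                text = line[10:].strip().rstrip(";")
                for key, value in _METHOD_MAP.items():
                    if key in text:
                        method = value
                        break
            elif rec == "AUTHOR":
                chunk = line[10:].strip()
                authors = (authors + chunk) if authors else chunk
            elif rec == "REMARK" and "FREE R VALUE" in line and ":" in line \
                    and "ERROR" not in line and "TEST" not in line:
                try:
                    r_free = float(line.split(":")[1].strip().rstrip("."))
                except ValueError:
                    pass
    return method, r_free, authors


def read_structure(path, chain: str,
                   uniprot_id: Optional[str] = None) -> StructureRecord:
    """Read one chain of a PDB/mmCIF file into a :class:`StructureRecord`.

    Residues named SEP/TPO/PTR/HIP/NEP are stored under their parent residue
    code with ``phospho_code`` set.  All models of a multi-model (NMR) file
    are retained.  Raises ``FileNotFoundError``/``ValueError`` on unreadable
    input and ``KeyError`` if the chain is absent.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()

    models: List[List[ResidueRecord]] = []
    for model in st:
        ch = model.find_chain(chain)
        if ch is None:
            raise KeyError(f"chain {chain!r} not found in {path}")
        residues = []
        for res in ch:
            name = res.name.strip().upper()
            if name in PHOSPHO_PARENT:
                aa3, code = PHOSPHO_PARENT[name], name
            elif name in THREE_TO_ONE:
                aa3, code = name, "none"
            else:
                continue  # waters, ligands
            atoms = {}
            for atom in res:
                if atom.element.name != "H":
                    atoms[atom.name.strip()] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
            residues.append(ResidueRecord(res.seqid.num, aa3, atoms, code))
        residues.sort(key=lambda r: r.author_index)
        models.append(residues)

    method, r_free, raw_authors = (None, None, None)
    if path.suffix.lower() in (".pdb", ".ent"):
        method, r_free, raw_authors = _scan_pdb_header(path)
    if method is None and len(models) > 1:
        method = "nmr"

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if raw_authors:
        last_author = raw_authors.split(",")[-1].strip()
    elif st.meta.authors:
        last_author = st.meta.authors[-1]
    else:
        last_author = None

    return StructureRecord(
        structure_id=f"{path.stem}_{chain}",
        uniprot_id=uniprot_id,
        models=models,
        method=method,
        resolution=resolution,
        r_free=r_free,
        last_author=last_author,
    )


# ---------------------------------------------------------------------------
# alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def align_residue_pair(a: StructureRecord, b: StructureRecord) -> ResidueMap:
    """Global Needleman–Wunsch alignment (BLOSUM62, gap open −10, extend −0.5).

    The returned map lists only match columns (no gaps).  ``identity`` is the
    fraction of aligned columns with identical residues; ``similarity`` the
    fraction with a positive BLOSUM62 score.
    """
    seq_a, seq_b = a.sequence, b.sequence
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: List[Tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))
    n_ident = sum(seq_a[i] == seq_b[j] for i, j in pairs)
    n_pos = sum(_BLOSUM62[seq_a[i], seq_b[j]] > 0 for i, j in pairs)
    n = len(pairs)
    return ResidueMap(pairs,
                      identity=n_ident / n if n else 0.0,
                      similarity=n_pos / n if n else 0.0)


# ---------------------------------------------------------------------------
# grouping and curation


def build_phosphosite_groups(
        structures: Sequence[StructureRecord]) -> List[PhosphositeGroup]:
    """Pair phosphorylated with non-phosphorylated structures per protein.

    One group is formed per (UniProt accession, exact phosphosite set); a
    structure phosphorylated at {A, B} belongs to the multisite group {A, B}
    only, so multisite events count as a single data point.  The
    non-phosphorylated partners of a group are the same-protein structures
    carrying no phosphate at any of the group's sites.  Groups lacking either
    state are dropped.
    """
    by_uniprot: Dict[str, List[StructureRecord]] = {}
    for s in structures:
        if s.uniprot_id is None:
            raise ValueError(f"{s.structure_id}: uniprot_id required")
        by_uniprot.setdefault(s.uniprot_id, []).append(s)

    groups: List[PhosphositeGroup] = []
    for uniprot, recs in by_uniprot.items():
        site_sets = sorted({s.phospho_sites for s in recs if s.phospho_sites},
                           key=sorted)
        for sites in site_sets:
            phos = [s for s in recs if s.phospho_sites == sites]
            non = [s for s in recs if not (s.phospho_sites & sites)]
            if phos and non:
                groups.append(PhosphositeGroup(uniprot, sites, phos, non))
    return groups


@dataclass
class CurationThresholds:
    resolution: float = 3.0   # Å, X-ray/EM only
    r_free: float = 0.3
    coverage: float = 0.25    # vs reference sequence
    similarity: float = 0.75  # median pairwise similarity


@dataclass
class RejectionRecord:
    structure_id: str
    state: str
    reason: str
    value: Optional[float] = None


def _coverage(record: StructureRecord, reference: str) -> float:
    ref = StructureRecord("ref", None, [[
        ResidueRecord(i + 1, _one_to_three(c), {}) for i, c in enumerate(reference)
    ]])
    m = align_residue_pair(record, ref)
    return len(m.pairs) / len(reference)


def _one_to_three(c: str) -> str:
    for aa3, one in THREE_TO_ONE.items():
        if one == c:
            return aa3
    return "UNK"


def curate_group(group: PhosphositeGroup,
                 thresholds: CurationThresholds = CurationThresholds(),
                 reference_sequence: Optional[str] = None,
                 ) -> Tuple[Optional[PhosphositeGroup], List[RejectionRecord]]:
    """Apply quality, coverage and consistency filters to a group.

    X-ray/EM structures failing the resolution or R-free bound are dropped
    (NMR is exempt: those fields are not defined for it).  Coverage is the
    aligned fraction of the reference sequence (the longest structure-derived
    sequence when no reference is given); each structure's median pairwise
    sequence similarity against the rest of the group must also pass.
    Returns ``(curated group or None, rejection log)``.
    """
    log: List[RejectionRecord] = []
    states = [("P", s) for s in group.phospho_structures] + \
             [("NP", s) for s in group.nonphospho_structures]

    kept = []
    for state, s in states:
        if s.method in ("xray", "em"):
            if s.resolution is not None and s.resolution > thresholds.resolution:
                log.append(RejectionRecord(s.structure_id, state,
                                           "resolution", s.resolution))
                continue
            if s.r_free is not None and s.r_free > thresholds.r_free:
                log.append(RejectionRecord(s.structure_id, state,
                                           "r_free", s.r_free))
                continue
        kept.append((state, s))

    if kept:
        reference = reference_sequence or max(
            (s.sequence for _, s in kept), key=len)
        survivors = []
        for state, s in kept:
            cov = _coverage(s, reference)
            if cov < thresholds.coverage:
                log.append(RejectionRecord(s.structure_id, state,
                                           "coverage", cov))
            else:
                survivors.append((state, s))
        kept = survivors

    if len(kept) > 1:
        sims = {}
        recs = [s for _, s in kept]
        for i, a in enumerate(recs):
            vals = [align_residue_pair(a, b).similarity
                    for j, b in enumerate(recs) if j != i]
            sims[a.structure_id] = float(np.median(vals))
        survivors = []
        for state, s in kept:
            if sims[s.structure_id] < thresholds.similarity:
                log.append(RejectionRecord(s.structure_id, state,
                                           "median_similarity",
                                           sims[s.structure_id]))
            else:
                survivors.append((state, s))
        kept = survivors

    phos = [s for st, s in kept if st == "P"]
    non = [s for st, s in kept if st == "NP"]
    if not phos or not non:
        return None, log
    return PhosphositeGroup(group.uniprot_id, group.site_indices, phos, non), log


def curation_report_rows(group: PhosphositeGroup,
                         curated: Optional[PhosphositeGroup],
                         log: List[RejectionRecord]) -> List[dict]:
    """Rows for the curation report TSV."""
    rejected = {r.structure_id: r for r in log}
    rows = []
    for state, s in [("P", x) for x in group.phospho_structures] + \
                    [("NP", x) for x in group.nonphospho_structures]:
        rej = rejected.get(s.structure_id)
        rows.append({
            "structure_id": s.structure_id,
            "uniprot_id": s.uniprot_id,
            "state": state,
            "method": s.method,
            "resolution": s.resolution,
            "r_free": s.r_free,
            "retained": rej is None and curated is not None,
            "reason": rej.reason if rej else "",
        })
    return rows
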