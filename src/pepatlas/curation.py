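"""Curation of peptide/HLA-I coordinate files into standardized complexes.

Raw PDB/mmCIF entries arrive with arbitrary chain naming, author numbering,
extra molecules (TCRs, antibodies, waters' parent chains) and varying
completeness.  The pipeline classifies chains by sequence (heavy chain by
>50% global identity to a 180-residue reference platform, β2-microglobulin
likewise, peptide by length 8-10), applies quality filters (resolution
≤ 3.0 Å, no unrelated chain within 5 Å of the peptide, complete non-zero
occupancy peptide backbone, ≥180 heavy-chain residues), trims the heavy
chain to its first 180 residues (the α1/α2 platform), renumbers platform
1-180 and peptide 1-n, types the HLA allotype against a reference allele
FASTA, and emits standardized complexes (platform chain "A", peptide chain
"C") plus a dataset summary FASTA and a rejection log.

Remote structure retrieval and rebuilding of missing N-terminal platform
residues are out of scope: input is a directory of local files, and entries
needing the rebuild are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .geometry import PeptideBackbone

__all__ = [
    "Atom",
    "ResidueRecord",
    "ChainRecord",
    "RawEntry",
    "ChainRole",
    "FilterDecision",
    "CuratedComplex",
    "read_entry",
    "classify_chains",
    "filter_entry",
    "renumber_and_trim",
    "type_hla",
    "write_summary_fasta",
    "read_summary_fasta",
    "read_reference_fasta",
    "curate_entry",
    "curate_directory",
]

PLATFORM_LENGTH = 180
PEPTIDE_LENGTHS = range(8, 11)
RESOLUTION_MAX = 3.0
CONTACT_CUTOFF = 5.0
IDENTITY_MIN = 0.5
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    name: str
    pos: np.ndarray
    occ: float = 1.0
    element: str = ""


@dataclass
class ResidueRecord:
    name: str           # 3-letter code
    seqid: int          # author numbering on input, 1-based after renumbering
    atoms: dict = field(default_factory=dict)  # atom name -> Atom

    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.name)
        if info is None or not info.is_amino_acid():
            return "X"
        return info.one_letter_code.upper()

    def has_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class ChainRecord:
    chain_id: str
    residues: list

    def sequence(self) -> str:
        return "".join(r.one_letter() for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for r in self.residues for a in r.atoms.values()])


@dataclass
class RawEntry:
    pdb_id: str
    chains: list
    resolution: float
    release_date: str
    experiment_type: str = ""

    def chain(self, chain_id: str) -> ChainRecord:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)


@dataclass
class ChainRole:
    role: str                      # heavy_chain | b2m | peptide | other
    identity_to_reference: float = 0.0


def read_entry(path) -> RawEntry:
    """Parse a PDB or mmCIF file into a RawEntry.

    Hydrogens and waters are dropped; of alternate conformations only the
    blank or 'A' altloc is kept, before any occupancy check.  Only the first
    model is considered.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable coordinates in {path.name}: {exc}") from exc
    st.remove_hydrogens()
    st.remove_waters()
    chains = []
    for chain in st[0]:
        residues = []
        for res in chain:
            if gemmi.find_tabulated_residue(res.name) is None or not gemmi.find_tabulated_residue(res.name).is_amino_acid():
                continue
            atoms = {}
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms[atom.name] = Atom(
                    name=atom.name,
                    pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occ=float(atom.occ),
                    element=atom.element.name,
                )
            if atoms:
                residues.append(ResidueRecord(res.name, res.seqid.num, atoms))
        if residues:
            chains.append(ChainRecord(chain.name, residues))
    info = dict(st.info)
    date = info.get("_pdbx_database_status.recvd_initial_deposition_date", "")
    return RawEntry(
        pdb_id=(info.get("_entry.id") or path.stem).upper(),
        chains=chains,
        resolution=float(st.resolution),
        release_date=date,
        experiment_type=info.get("_exptl.method", ""),
    )


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def alignment_identity(seq: str, reference: str) -> float:
    """Global-alignment identity: matches / reference length."""
    if not seq or not reference:
        return 0.0
    seq = "".join(c for c in seq if c != "X") or "A"
    aln = _get_aligner().align(reference, seq)[0]
    matches = 0
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        a = aln.target[r0:r1]
        b = aln.query[q0:q1]
        matches += sum(x == y for x, y in zip(a, b))
    return matches / len(reference)


def classify_chains(entry: RawEntry, reference_heavy: str,
                    reference_b2m: str = "") -> dict[str, ChainRole]:
    """Assign each chain a role: heavy_chain, b2m, peptide or other."""
    if not reference_heavy:
        raise ValueError("reference heavy-chain sequence required")
    roles: dict[str, ChainRole] = {}
    for chain in entry.chains:
        seq = chain.sequence()
        ident_h = alignment_identity(seq, reference_heavy)
        if ident_h > IDENTITY_MIN:
            roles[chain.chain_id] = ChainRole("heavy_chain", ident_h)
            continue
        if reference_b2m:
            ident_b = alignment_identity(seq, reference_b2m)
            if ident_b > IDENTITY_MIN:
                roles[chain.chain_id] = ChainRole("b2m", ident_b)
                continue
        if len(chain.residues) in PEPTIDE_LENGTHS:
            roles[chain.chain_id] = ChainRole("peptide")
        else:
            roles[chain.chain_id] = ChainRole("other")
    return roles


def _first_chain_with_role(entry: RawEntry, roles, role: str):
    for ch in entry.chains:
        if roles.get(ch.chain_id) and roles[ch.chain_id].role == role:
            return ch
    return None


@dataclass
class FilterDecision:
    accepted: bool
    reasons: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def filter_entry(entry: RawEntry, roles: dict[str, ChainRole],
                 resolution_max: float = RESOLUTION_MAX,
                 reference_heavy: str = "") -> FilterDecision:
    """Apply the retention filters to a classified entry.

    Rejection reasons accumulate rather than short-circuiting, so the log
    shows everything wrong with an entry.  Zero-occupancy heavy-chain atoms
    only warn; 1-2 missing N-terminal platform residues set the rebuild flag
    (the rebuild itself is not performed, so such entries are excluded).
    """
    reasons: list[str] = []
    flags: dict = {}

    heavy = _first_chain_with_role(entry, roles, "heavy_chain")
    peptide = _first_chain_with_role(entry, roles, "peptide")
    if heavy is None:
        reasons.append("no_heavy_chain")
    if peptide is None:
        reasons.append("no_peptide")
    if entry.resolution > resolution_max:
        reasons.append("resolution_above_max")

    if peptide is not None:
        pep_xyz = peptide.coords()
        for ch in entry.chains:
            role = roles.get(ch.chain_id)
            if role is None or role.role != "other":
                continue
            d = np.linalg.norm(
                ch.coords()[:, None, :] - pep_xyz[None, :, :], axis=2
            ).min()
            if d < CONTACT_CUTOFF:
                reasons.append("other_chain_contact")
                break
        for res in peptide.residues:
            if not res.has_complete_backbone():
                reasons.append("peptide_backbone_incomplete")
                break
            if any(res.atoms[a].occ <= 0.0 for a in BACKBONE_ATOMS):
                reasons.append("peptide_zero_occupancy")
                break

    if heavy is not None:
        if any(a.occ <= 0.0 for r in heavy.residues for a in r.atoms.values()):
            flags["heavy_chain_occupancy_warning"] = True
        if len(heavy.residues) < PLATFORM_LENGTH:
            missing = PLATFORM_LENGTH - len(heavy.residues)
            nterm_gap = None
            if reference_heavy:
                aln = _get_aligner().align(reference_heavy, heavy.sequence())[0]
                nterm_gap = aln.aligned[0][0][0]  # first aligned ref position
            if missing in (1, 2) and (nterm_gap is None or nterm_gap == missing):
                flags["rebuilt_nterm_needed"] = True
                reasons.append("heavy_chain_missing_nterm")
            else:
                reasons.append("heavy_chain_short")

    return FilterDecision(accepted=not reasons, reasons=reasons, flags=flags)


@dataclass
class CuratedComplex:
    """A standardized peptide/platform complex.

    platform: exactly 180 residues renumbered 1-180 (chain "A" on output);
    peptide: n residues renumbered 1-n (chain "C").
    """

    pdb_id: str
    platform: list
    peptide: list
    allotype: str
    resolution: float
    release_date: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.platform) != PLATFORM_LENGTH:
            raise ValueError(
                f"platform must have exactly {PLATFORM_LENGTH} residues, got {len(self.platform)}"
            )

    def platform_sequence(self) -> str:
        return "".join(r.one_letter() for r in self.platform)

    def peptide_sequence(self) -> str:
        return "".join(r.one_letter() for r in self.peptide)

    def platform_ca(self, position: int) -> np.ndarray:
        res = self.platform[position - 1]
        return res.atoms["CA"].pos

    def platform_ca_array(self) -> np.ndarray:
        return np.array([r.atoms["CA"].pos for r in self.platform])

    def peptide_backbone(self) -> PeptideBackbone:
        coords = np.array(
            [[r.atoms[a].pos for a in BACKBONE_ATOMS] for r in self.peptide]
        )
        return PeptideBackbone(self.peptide_sequence(), coords)

    def release_year(self) -> int:
        return int(self.release_date[:4])

    def to_structure(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.pdb_id
        st.resolution = self.resolution
        if self.release_date:
            st.info["_pdbx_database_status.recvd_initial_deposition_date"] = self.release_date
        st.info["_entry.id"] = self.pdb_id
        model = gemmi.Model("1")
        for cid, residues in (("A", self.platform), ("C", self.peptide)):
            chain = gemmi.Chain(cid)
            for res in residues:
                r = gemmi.Residue()
                r.name = res.name
                r.seqid = gemmi.SeqId(res.seqid, " ")
                for atom in res.atoms.values():
                    a = gemmi.Atom()
                    a.name = atom.name
                    a.pos = gemmi.Position(*atom.pos)
                    a.occ = atom.occ
                    a.element = gemmi.Element(atom.element or atom.name[0])
                    r.add_atom(a)
                chain.add_residue(r)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path) -> None:
        self.to_structure().write_pdb(str(path))


def renumber_and_trim(entry: RawEntry, roles: dict[str, ChainRole],
                      allotype: str = "") -> CuratedComplex:
    """Trim the heavy chain to its first 180 residues and renumber both chains."""
    heavy = _first_chain_with_role(entry, roles, "heavy_chain")
    peptide = _first_chain_with_role(entry, roles, "peptide")
    if heavy is None or peptide is None:
        raise ValueError("entry lacks a heavy chain or peptide")
    if len(heavy.residues) < PLATFORM_LENGTH:
        raise ValueError("heavy chain shorter than the 180-residue platform")
    platform = [
        ResidueRecord(r.name, i + 1, dict(r.atoms))
        for i, r in enumerate(heavy.residues[:PLATFORM_LENGTH])
    ]
    pep = [
        ResidueRecord(r.name, i + 1, dict(r.atoms))
        for i, r in enumerate(peptide.residues)
    ]
    return CuratedComplex(
        pdb_id=entry.pdb_id,
        platform=platform,
        peptide=pep,
        allotype=allotype,
        resolution=entry.resolution,
        release_date=entry.release_date,
    )


def load_curated(path) -> CuratedComplex:
    """Read back a curated complex written by :meth:`CuratedComplex.write_pdb`.

    Chains are positional: "A" is the platform, "C" the peptide.  The
    allotype is not stored in coordinates; callers needing it should keep
    the summary FASTA alongside.
    """
    entry = read_entry(path)
    platform = entry.chain("A").residues
    peptide = entry.chain("C").residues
    return CuratedComplex(
        pdb_id=entry.pdb_id,
        platform=platform,
        peptide=peptide,
        allotype="",
        resolution=entry.resolution,
        release_date=entry.release_date,
    )


def read_reference_fasta(path) -> dict[str, str]:
    """Allele name -> sequence.  Names are the first '|'-free token of the header."""
    refs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        refs[rec.id] = str(rec.seq)
    if not refs:
        raise ValueError(f"no records in reference FASTA {path}")
    return refs


def type_hla(platform_sequence: str, references: dict[str, str]) -> tuple[str, float]:
    """Assign the reference allele with maximal alignment identity.

    Ties break to the lexicographically smallest allele name.  Identity at or
    below 50% is a typing failure.
    """
    if not references:
        raise ValueError("empty allele reference set")
    best_name, best_ident = None, -1.0
    for name in sorted(references):
        ident = alignment_identity(platform_sequence, references[name])
        if ident > best_ident:
            best_name, best_ident = name, ident
    if best_ident <= IDENTITY_MIN:
        raise ValueError(
            f"HLA typing failed: best identity {best_ident:.2f} (<= {IDENTITY_MIN}) for {best_name}"
        )
    return best_name, best_ident


def write_summary_fasta(complexes) -> str:
    """Dataset summary: per complex one HLA and one peptide record.

    Header fields, '|'-delimited: PDB ID, chain name, allele, release date,
    resolution.
    """
    lines = []
    for cx in complexes:
        for chain_name, seq in (("hla", cx.platform_sequence()),
                                ("peptide", cx.peptide_sequence())):
            lines.append(
                f">{cx.pdb_id}|{chain_name}|{cx.allotype}|{cx.release_date}|{cx.resolution:g}"
            )
            lines.append(seq)
    return "\n".join(lines) + ("\n" if lines else "")


def read_summary_fasta(text: str):
    """Inverse of write_summary_fasta: list of metadata+sequence dicts."""
    records = []
    header = None
    for line in text.splitlines():
        if line.startswith(">"):
            header = line[1:]
        elif header is not None:
            pdb_id, chain, allele, date, res = header.split("|")
            records.append(
                {
                    "pdb_id": pdb_id,
                    "chain": chain,
                    "allele": allele,
                    "release_date": date,
                    "resolution": float(res),
                    "sequence": line,
                }
            )
            header = None
    return records


def curate_entry(path, references: dict[str, str],
                 reference_b2m: str = "",
                 resolution_max: float = RESOLUTION_MAX):
    """End-to-end curation of one coordinate file.

    Returns (CuratedComplex, decision) on acceptance or (None, decision) on
    rejection.  The heavy-chain classification reference is the
    lexicographically smallest allele in ``references`` (any platform
    sequence >50% identical to one reference is >50% identical in spirit to
    all; the exact allele is then assigned by typing).
    """
    reference_heavy = references[sorted(references)[0]]
    try:
        entry = read_entry(path)
    except ValueError:
        return None, FilterDecision(False, ["parse_error"])
    roles = classify_chains(entry, reference_heavy, reference_b2m)
    decision = filter_entry(entry, roles, resolution_max, reference_heavy)
    if not decision.accepted:
        return None, decision
    curated = renumber_and_trim(entry, roles)
    try:
        allotype, ident = type_hla(curated.platform_sequence(), references)
    except ValueError:
        decision.accepted = False
        decision.reasons.append("typing_failure")
        return None, decision
    curated.allotype = allotype
    curated.flags.update(decision.flags)
    curated.flags["typing_identity"] = ident
    return curated, decision


def curate_directory(in_dir, references: dict[str, str],
                     reference_b2m: str = "",
                     resolution_max: float = RESOLUTION_MAX):
    """Curate every .pdb/.cif file in a directory.

    Returns (complexes, rejection_rows) where rejection_rows are
    (filename, comma-joined reasons) tuples for the TSV log.
    """
    complexes, rejections = [], []
    paths = sorted(
        p for p in Path(in_dir).iterdir() if p.suffix.lower() in (".pdb", ".cif", ".ent")
    )
    for p in paths:
        curated, decision = curate_entry(p, references, reference_b2m, resolution_max)
        if curated is not None:
            complexes.append(curated)
        else:
            rejections.append((p.name, ",".join(decision.reasons)))
    return complexes, rejections
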