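"""Extraction and comparison of phosphotransfer specificity residues.

A small set of co-evolving interface residues governs partner choice in
His-Asp phosphotransfer: six on the phosphodonor side (the HisKA
dimerization/phosphotransfer helix hairpin; Spo0B is treated with the same
profile because its four-helix bundle presents an equivalent interface) and
seven on the receiver (REC) side.  Residues are read off a local alignment of
the target protein against a panel of reference domains, anchored on the
conserved phospho-accepting residue (His for HisKA-like proteins, Asp for
receivers); the signature positions are fixed offsets from the anchor in
reference coordinates, shipped as profile data rather than code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import AlignParams, LocalAlignment, align_local
from .model import SpecificitySignature

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ROLE_LENGTH = {"HISKA_LIKE": 6, "REC": 7}
ANCHOR_RESIDUE = {"HISKA_LIKE": "H", "REC": "D"}


@dataclass(frozen=True)
class ReferenceDomain:
    name: str
    sequence: str
    anchor_pos: int  # 1-based position of the conserved His/Asp

    def __post_init__(self) -> None:
        if not (1 <= self.anchor_pos <= len(self.sequence)):
            raise ValueError(f"{self.name}: anchor outside sequence")


@dataclass(frozen=True)
class SpecificityProfile:
    """Reference domains plus anchor-relative signature offsets."""

    profile_id: str
    role: str  # "HISKA_LIKE" or "REC"
    references: tuple[ReferenceDomain, ...]
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != ROLE_LENGTH[self.role]:
            raise ValueError(
                f"{self.role} profile needs {ROLE_LENGTH[self.role]} offsets, "
                f"got {len(self.offsets)}"
            )
        want = ANCHOR_RESIDUE[self.role]
        for ref in self.references:
            have = ref.sequence[ref.anchor_pos - 1]
            if have != want:
                raise ValueError(
                    f"{ref.name}: anchor residue {have!r} is not the conserved {want}"
                )


def extract_signature(
    seq: str,
    profile: SpecificityProfile,
    gene_id: str = "",
    align_params: AlignParams = AlignParams(),
    min_score: float = 40.0,
) -> SpecificitySignature:
    """Read the specificity residues of one protein.

    The target is aligned locally against every reference; the best-scoring
    alignment (ties broken by reference order) maps the reference anchor onto
    the target, and residues are read at the profile offsets through the
    alignment.  Positions falling in gaps or off the protein yield ``'-'``
    and a ``gapped_position`` flag; if no reference alignment reaches
    ``min_score`` or maps the anchor, an all-gap signature flagged
    ``no_anchor`` is returned.
    """
    if not seq:
        raise ValueError("empty sequence")
    width = ROLE_LENGTH[profile.role]
    scored: list[tuple[float, ReferenceDomain, LocalAlignment]] = []
    for order, ref in enumerate(profile.references):
        aln = align_local(ref.sequence, seq, align_params)
        if aln is not None and aln.score >= min_score:
            scored.append((aln.score, order, ref, aln))  # type: ignore[arg-type]
    scored.sort(key=lambda t: (-t[0], t[1]))
    for score, _order, ref, aln in scored:  # fall through refs whose anchor is gapped
        anchor0 = ref.anchor_pos - 1
        target_anchor = aln.target_position_of(anchor0)
        if target_anchor is None:
            continue
        flags: set[str] = set()
        residues = []
        for off in profile.offsets:
            tpos = aln.target_position_of(anchor0 + off)
            if tpos is None or not (0 <= tpos < len(seq)):
                residues.append("-")
                flags.add("gapped_position")
            else:
                residues.append(seq[tpos])
        if scored[0][2] is not ref:
            flags.add("low_confidence_anchor")
        return SpecificitySignature(
            gene_id=gene_id,
            role=profile.role,
            residues="".join(residues),
            anchor_position=target_anchor + 1,
            alignment_score=score,
            flags=flags,
        )
    return SpecificitySignature(
        gene_id=gene_id,
        role=profile.role,
        residues="-" * width,
        anchor_position=-1,
        alignment_score=scored[0][0] if scored else 0.0,
        flags={"no_anchor"},
    )


def hamming(sig_a: SpecificitySignature | str, sig_b: SpecificitySignature | str) -> int:
    """Number of differing positions between two equal-length signatures.

    ``'-'`` mismatches every residue; two gaps match.
    """
    a = sig_a.residues if isinstance(sig_a, SpecificitySignature) else sig_a
    b = sig_b.residues if isinstance(sig_b, SpecificitySignature) else sig_b
    if isinstance(sig_a, SpecificitySignature) and isinstance(sig_b, SpecificitySignature):
        if sig_a.role != sig_b.role:
            raise ValueError(f"role mismatch: {sig_a.role} vs {sig_b.role}")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {a!r} vs {b!r}")
    return sum(1 for x, y in zip(a, b) if x != y)


def position_frequency_matrix(
    sigs: Sequence[SpecificitySignature], role: str | None = None
) -> pd.DataFrame:
    """Counts of amino acids per signature position (gaps excluded).

    Rows are 1-based signature positions; columns the 20 amino acids.
    Column sums per row equal the number of non-gap observations at that
    position.  The table is directly consumable by sequence-logo tools.
    """
    roles = {s.role for s in sigs}
    if len(roles) > 1:
        raise ValueError(f"mixed roles: {sorted(roles)}")
    if not sigs:
        warnings.warn("no signatures; returning zero matrix", stacklevel=2)
        width = ROLE_LENGTH[role] if role else 0
    else:
        width = ROLE_LENGTH[roles.pop()]
    counts = np.zeros((width, len(AMINO_ACIDS)), dtype=int)
    col = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for s in sigs:
        for i, aa in enumerate(s.residues):
            if aa in col:
                counts[i, col[aa]] += 1
    return pd.DataFrame(counts, index=range(1, width + 1), columns=list(AMINO_ACIDS))


def group_distance_summary(
    groups: Mapping[str, Sequence[SpecificitySignature]]
) -> pd.DataFrame:
    """Mean pairwise Hamming distances within and between signature groups.

    A symmetric labels-by-labels table; the diagonal holds within-group means
    over unordered distinct pairs (NaN for singleton groups).  This is the
    package's declared summary statistic for comparing signature similarity
    across taxonomic or architectural groupings.
    """
    labels = list(groups)
    for label, sigs in groups.items():
        if not sigs:
            raise ValueError(f"group {label!r} is empty")
        if len({len(s.residues) for s in sigs}) > 1:
            raise ValueError(f"group {label!r} mixes signature lengths")
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        for lb in labels[i:]:
            if la == lb:
                sigs = list(groups[la])
                pairs = [
                    hamming(sigs[x], sigs[y])
                    for x in range(len(sigs))
                    for y in range(x + 1, len(sigs))
                ]
                mat.loc[la, la] = float(np.mean(pairs)) if pairs else np.nan
            else:
                pairs = [hamming(a, b) for a in groups[la] for b in groups[lb]]
                mat.loc[la, lb] = mat.loc[lb, la] = float(np.mean(pairs))
    return mat


# -- profile file I/O ----------------------------------------------------

def load_profile(fasta_path: str | Path, meta_path: str | Path) -> SpecificityProfile:
    """Load a profile from a reference FASTA and its sidecar TSV.

    The sidecar has columns ``field``, ``name``, ``value`` with one
    ``profile`` row (name = profile id, value = role), one ``anchor`` row per
    reference (value = 1-based anchor position) and one ``offset`` row per
    signature position (name = rank, value = signed offset).
    """
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    prof_rows = meta[meta["field"] == "profile"]
    if len(prof_rows) != 1:
        raise ValueError(f"{meta_path}: need exactly one profile row")
    profile_id = prof_rows.iloc[0]["name"]
    role = prof_rows.iloc[0]["value"]
    anchors = {
        r["name"]: int(r["value"]) for _, r in meta[meta["field"] == "anchor"].iterrows()
    }
    offsets = tuple(
        int(r["value"])
        for _, r in meta[meta["field"] == "offset"]
        .astype({"name": int})
        .sort_values("name")
        .iterrows()
    )
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in anchors:
            raise ValueError(f"no anchor recorded for reference {rec.id!r}")
        refs.append(ReferenceDomain(rec.id, str(rec.seq).upper(), anchors[rec.id]))
    return SpecificityProfile(profile_id, role, tuple(refs), offsets)


def save_profile(profile: SpecificityProfile, fasta_path: str | Path, meta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for ref in profile.references:
            fh.write(f">{ref.name}\n{ref.sequence}\n")
    rows = [dict(field="profile", name=profile.profile_id, value=profile.role)]
    rows += [
        dict(field="anchor", name=ref.name, value=str(ref.anchor_pos))
        for ref in profile.references
    ]
    rows += [
        dict(field="offset", name=str(i), value=str(off))
        for i, off in enumerate(profile.offsets)
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def signatures_table(sigs: Iterable[SpecificitySignature]) -> pd.DataFrame:
    rows = [
        dict(
            gene_id=s.gene_id,
            role=s.role,
            residues=s.residues,
            anchor_position=s.anchor_position,
            alignment_score=s.alignment_score,
            flags=",".join(sorted(s.flags)),
        )
        for s in sigs
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "role", "residues", "anchor_position", "alignment_score", "flags"]
    )
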