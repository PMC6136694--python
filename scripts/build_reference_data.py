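"""Deterministically (re)build the synthetic reference data shipped in
``src/spo0scan/data``.

All sequence files produced here are SYNTHETIC stand-ins, generated from a
fixed seed: HisKA-like and REC-like reference scaffolds for the specificity
profiles, a Spo0B N-terminal reference, and a set of tagged protein
constructs carrying the published specificity-residue strings planted at the
profile offsets.  They exercise the anchored-alignment machinery with known
ground truth; they are not the natural E. coli / B. subtilis sequences.

Run from the repository root:  python scripts/build_reference_data.py
"""

from __future__ import annotations

import sys
import zlib
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from spo0scan.specificity import (  # noqa: E402
    ReferenceDomain,
    SpecificityProfile,
    save_profile,
)

DATA = ROOT / "src" / "spo0scan" / "data"
AA = "ACDEFGHIKLMNPQRSTVWY"

HISKA_ANCHOR = 20  # 1-based
HISKA_LEN = 70
HISKA_OFFSETS = (3, 4, 7, 8, 11, 12)
REC_ANCHOR = 55  # 1-based
REC_LEN = 115
REC_OFFSETS = (5, 6, 9, 10, 13, 56, 57)

# construct name -> (role, published specificity residues)
CONSTRUCT_SIGNATURES = {
    "BsKinA": ("HISKA_LIKE", "TAGFQL"),
    "Bs0F": ("REC", "QGILEVD"),
    "Bs0B": ("HISKA_LIKE", "QLGNSL"),
    "Bs0A": ("REC", "NELLEYD"),
    "Dt1918": ("HISKA_LIKE", "TTGFQL"),
    "Dt0F": ("REC", "QGILEVD"),
    "Dt0B": ("HISKA_LIKE", "QVGLQL"),
    "Dt0A": ("REC", "NEFLDFD"),
    "Ca0903": ("HISKA_LIKE", "NISAQL"),
    "Ca3319": ("HISKA_LIKE", "SVGLQL"),
    "Ca0A": ("REC", "NEFIDYD"),
}

TAG = "MGSSHHHHHHSSGLVPRGSH"  # his-tag-like N-terminal fusion remnant


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float, protected: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA if a != out[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def plant(seq: str, anchor0: int, offsets, residues: str) -> str:
    out = list(seq)
    for off, aa in zip(offsets, residues):
        out[anchor0 + off] = aa
    return "".join(out)


def build_scaffolds(rng: np.random.Generator) -> tuple[str, str]:
    """Base HisKA-like and REC-like scaffolds with conserved anchor motifs."""
    hiska = list(random_protein(rng, HISKA_LEN))
    hiska[HISKA_ANCHOR - 1] = "H"
    # conserved helix motif downstream of the phospho-His
    for i, aa in enumerate("ELRTPL"):
        hiska[HISKA_ANCHOR + i] = aa
    rec = list(random_protein(rng, REC_LEN))
    rec[REC_ANCHOR - 1] = "D"
    for i, aa in enumerate("DD"):  # acidic pocket residues near the N-terminus
        rec[11 + i] = aa
    rec[101] = "K"  # conserved lysine
    return "".join(hiska), "".join(rec)


def main() -> None:
    rng = np.random.default_rng(4025)
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "profiles").mkdir(exist_ok=True)

    hiska_base, rec_base = build_scaffolds(rng)

    protected_h = {HISKA_ANCHOR - 1} | {HISKA_ANCHOR - 1 + o for o in HISKA_OFFSETS}
    protected_r = {REC_ANCHOR - 1} | {REC_ANCHOR - 1 + o for o in REC_OFFSETS}

    hiska_refs = tuple(
        ReferenceDomain(name, mutate(rng, hiska_base, 0.15, {HISKA_ANCHOR - 1}), HISKA_ANCHOR)
        for name in ("EnvZ_like", "RstB_like", "CpxA_like")
    )
    rec_refs = tuple(
        ReferenceDomain(name, mutate(rng, rec_base, 0.15, {REC_ANCHOR - 1}), REC_ANCHOR)
        for name in ("OmpR_like", "RstA_like", "CpxR_like")
    )
    save_profile(
        SpecificityProfile("hiska_synthetic", "HISKA_LIKE", hiska_refs, HISKA_OFFSETS),
        DATA / "profiles" / "hiska_synthetic.fasta",
        DATA / "profiles" / "hiska_synthetic.tsv",
    )
    save_profile(
        SpecificityProfile("rec_synthetic", "REC", rec_refs, REC_OFFSETS),
        DATA / "profiles" / "rec_synthetic.fasta",
        DATA / "profiles" / "rec_synthetic.tsv",
    )

    # Spo0B N-terminal reference: the first 50 residues of a Spo0B-like
    # protein built on the HisKA scaffold (Spo0B presents a HisKA-equivalent
    # four-helix-bundle interface).
    spo0b_nterm = mutate(rng, hiska_base[:50], 0.25, protected_h)
    with open(DATA / "spo0b_nterm_synthetic.fasta", "w") as fh:
        fh.write(">Spo0B_nterm_synthetic first 50 aa, synthetic stand-in\n")
        fh.write(spo0b_nterm + "\n")

    # synthetic stand-in for the 11 tagged expression constructs
    with open(DATA / "construct_panel_synthetic.fasta", "w") as fh:
        for name, (role, residues) in CONSTRUCT_SIGNATURES.items():
            crng = np.random.default_rng([4025, zlib.crc32(name.encode())])
            if role == "HISKA_LIKE":
                core = mutate(crng, hiska_base, 0.12, protected_h)
                core = plant(core, HISKA_ANCHOR - 1, HISKA_OFFSETS, residues)
                seq = TAG + random_protein(crng, 30) + core + random_protein(crng, 40)
            else:
                core = mutate(crng, rec_base, 0.12, protected_r)
                core = plant(core, REC_ANCHOR - 1, REC_OFFSETS, residues)
                seq = TAG + random_protein(crng, 8) + core + random_protein(crng, 25)
            fh.write(f">{name} synthetic stand-in construct\n{seq}\n")

    # published specificity residues (survey table fixture)
    rows = [
        "species\tlocus\tcomponent\tpas\tresidues",
        "Bacillus subtilis\tKinA\tkinase\tyes\tTAGFQL",
        "Bacillus subtilis\tKinB\tkinase\tno\tTVGFQL",
        "Bacillus subtilis\tKinC\tkinase\tyes\tTSGFQI",
        "Bacillus subtilis\tKinD\tkinase\tno\tTGGFQL",
        "Bacillus subtilis\tKinE\tkinase\tyes\tTAGFQL",
        "Bacillus subtilis\tSpo0F\tspo0f\t\tQGILEVD",
        "Bacillus subtilis\tSpo0B\tspo0b\t\tQLGNSL",
        "Bacillus subtilis\tSpo0A\tspo0a\t\tNELLEYD",
        "Desulfotomaculum acetoxidans\tDtox_0091\tkinase\tyes\tTTGFQM",
        "Desulfotomaculum acetoxidans\tDtox_1564\tkinase\tno\tTAAFEL",
        "Desulfotomaculum acetoxidans\tDtox_1918\tkinase\tyes\tTTGFQL",
        "Desulfotomaculum acetoxidans\tDtox_2569\tkinase\tyes\tTTGFQM",
        "Desulfotomaculum acetoxidans\tDtox_3081\tkinase\tyes\tTTGFQF",
        "Desulfotomaculum acetoxidans\tDtox_3426\tkinase\tyes\tTTGFQL",
        "Desulfotomaculum acetoxidans\tDtox_3834\tkinase\tyes\tTTGFQM",
        "Desulfotomaculum acetoxidans\tSpo0F\tspo0f\t\tQGILEVD",
        "Desulfotomaculum acetoxidans\tSpo0B\tspo0b\t\tQVGLQL",
        "Desulfotomaculum acetoxidans\tSpo0A\tspo0a\t\tNEFLDFD",
        "Clostridium acetobutylicum\tCA_C0323\tkinase\tno\tNVSAQV",
        "Clostridium acetobutylicum\tCA_C0903\tkinase\tyes\tNISAQL",
        "Clostridium acetobutylicum\tCA_C3319\tkinase\tno\tSVGLQL",
        "Clostridium acetobutylicum\tSpo0A\tspo0a\t\tNEFIDYD",
    ]
    (DATA / "published_signatures.tsv").write_text("\n".join(rows) + "\n")

    # expected residue strings for the synthetic constructs
    lines = ["construct\trole\tresidues"]
    lines += [f"{n}\t{r}\t{s}" for n, (r, s) in CONSTRUCT_SIGNATURES.items()]
    (DATA / "construct_panel_signatures.tsv").write_text("\n".join(lines) + "\n")

    print(f"wrote reference data under {DATA}")


if __name__ == "__main__":
    main()
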