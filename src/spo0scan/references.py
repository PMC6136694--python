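"""Loaders for the reference data shipped with the package.

All shipped sequence files are synthetic stand-ins built by
``scripts/build_reference_data.py`` from a fixed seed (see the file headers);
the published specificity-residue table transcribes the printed survey values
for B. subtilis, D. acetoxidans and C. acetobutylicum Spo0 proteins.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .specificity import SpecificityProfile, load_profile


def _data_path(*parts: str) -> Path:
    return Path(str(resources.files("spo0scan").joinpath("data", *parts)))


@lru_cache(maxsize=None)
def default_hiska_profile() -> SpecificityProfile:
    """Six-residue phosphodonor profile (sensor kinases and Spo0B)."""
    return load_profile(
        _data_path("profiles", "hiska_synthetic.fasta"),
        _data_path("profiles", "hiska_synthetic.tsv"),
    )


@lru_cache(maxsize=None)
def default_rec_profile() -> SpecificityProfile:
    """Seven-residue receiver profile (Spo0F, Spo0A and other REC proteins)."""
    return load_profile(
        _data_path("profiles", "rec_synthetic.fasta"),
        _data_path("profiles", "rec_synthetic.tsv"),
    )


@lru_cache(maxsize=None)
def spo0b_nterm_reference() -> str:
    """Synthetic stand-in for the Spo0B N-terminal (first 50 aa) reference."""
    rec = next(SeqIO.parse(str(_data_path("spo0b_nterm_synthetic.fasta")), "fasta"))
    return str(rec.seq)


def published_signatures() -> pd.DataFrame:
    """Printed specificity residues of the three experimentally studied genomes.

    Columns: species, locus, component (kinase/spo0f/spo0b/spo0a), pas
    (yes/no for kinase rows), residues.
    """
    df = pd.read_csv(_data_path("published_signatures.tsv"), sep="\t", dtype=str)
    return df.fillna("")


def construct_panel() -> dict[str, str]:
    """Synthetic stand-ins for the 11 tagged expression-construct proteins."""
    return {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(_data_path("construct_panel_synthetic.fasta")), "fasta")
    }


def construct_expected_signatures() -> pd.DataFrame:
    """Expected residue strings for each synthetic construct (from the
    published table)."""
    return pd.read_csv(_data_path("construct_panel_signatures.tsv"), sep="\t", dtype=str)
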