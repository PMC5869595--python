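"""Synthetic fixture generators for tests and demos.

These produce small, plain-text stand-ins for experimental inputs: AFM-style
protein-position tables (per-molecule positions along a DNA contour, in nm)
and tiny-lattice run configurations.  They emulate the format and first-bin
statistics of real position tables, not the microscopy itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observables import AFM_BIN_NM


def generate_afm_positions(n_molecules: int, bin_weights, seed: int,
                           bin_nm: float = AFM_BIN_NM) -> pd.DataFrame:
    """Sample synthetic protein positions along a DNA contour.

    ``bin_weights`` give the probability of each consecutive 50-nm bin
    (normalised internally); within a bin, positions are uniform.  Returns
    a table with ``molecule_id`` and ``position_nm`` columns, one protein
    per molecule.
    """
    w = np.asarray(bin_weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or (w < 0).any() or w.sum() <= 0:
        raise ValueError("bin_weights must be a non-empty non-negative vector")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    bins = rng.choice(w.size, size=n_molecules, p=w)
    offsets = rng.uniform(0.0, bin_nm, size=n_molecules)
    return pd.DataFrame({
        "molecule_id": np.arange(n_molecules),
        "position_nm": bins * bin_nm + offsets,
    })


def write_afm_fixture(path, n_molecules: int, bin_weights, seed: int) -> None:
    """Write a synthetic AFM position table as TSV."""
    generate_afm_positions(n_molecules, bin_weights, seed).to_csv(
        path, sep="\t", index=False)


def tiny_lattice_config(length_bp: int = 60, srs_offset_bp: int = 10,
                        srs_length_bp: int = 4) -> dict:
    """A small no-ATP run configuration suitable for oracle cross-checks."""
    return {
        "substrate": {
            "length_bp": length_bp,
            "srs_offset_bp": srs_offset_bp,
            "srs_length_bp": srs_length_bp,
            "triplex": "none",
        },
        "params": {
            "p_on_srs": 0.1, "p_on_ns": 0.1,
            "p_off_srs": 0.02, "p_off_ns": 0.05,
            "sld_srs_mean": 1.0, "sld_srs_sd": 0.25,
            "sld_ns_mean": 8.0, "sld_ns_sd": 2.0,
            "equilibration_mcs": 500, "sampling_mcs": 1500,
        },
        "scenario": "no_atp",
        "n_dna": 200,
        "seed": 0,
    }
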