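"""Loaders for the packaged deterministic fixture tables.

All fixtures are small plain TSV files shipped with the package; they are
constructed from the stage-wise constraints of the tea-fermentation study
(conversion ratios, taste-class ratios, calorimetric slopes) rather than
sampled from distributions.  The odor-threshold table is a synthetic
demonstration only and carries no physiological meaning.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_catechins",
    "load_amino_acids",
    "load_aa_classes",
    "load_calorimetry",
    "load_odor_thresholds",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("sonoflux.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_catechins() -> pd.DataFrame:
    """Catechin and caffeine contents (ug/g) per fermentation stage.

    Rows are samples PT-G ... PT-A; the (EGC+GA)/EGCG conversion ratio rises
    from 0.98 through 7.6 (PT-C), with 5.2 at PT-A, and caffeine is the
    constant inert tracer."""
    return _read("catechins_fixture.tsv", index_col="sample")


def load_amino_acids() -> pd.DataFrame:
    """Taste-active amino-acid log10 abundances (8 acids x 6 stages).

    Constructed so the linear-scale umami/sweet summed-abundance ratio is
    exactly 0.53 at PT-G and 1.02 at PT-A."""
    return _read("amino_acids_fixture.tsv", index_col="amino_acid")


def load_aa_classes() -> dict[str, str]:
    """Amino-acid to taste-class mapping (umami / sweet / bitter)."""
    df = _read("aa_classes.tsv")
    return dict(zip(df["amino_acid"], df["taste_class"]))


def load_calorimetry(power: float | None = None) -> pd.DataFrame:
    """Calorimetry traces (time_s, temperature_c) per power density.

    The initial slopes encode the energy-conversion coefficients
    (eta = 0.61 at 0.3 W/mL rising to 0.77 at 0.8 W/mL) for 100 g of water
    heated by P_input = power density x 100 mL."""
    df = _read("calorimetry_fixture.tsv")
    if power is not None:
        df = df[df["power"] == power].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no calorimetry trace at power {power}")
    return df


def load_odor_thresholds() -> pd.DataFrame:
    """Synthetic demonstration odor thresholds (not physiological)."""
    return _read("odor_thresholds_synthetic.tsv")
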