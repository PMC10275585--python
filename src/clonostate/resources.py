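"""Packaged reference tables and synthetic stand-in gene sets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .scoring import GeneSignature, InnatenessReference, read_signatures
from .simulate import DEFAULT_PROGRAMS


def _data_path(name: str):
    return resources.files("clonostate").joinpath("data", name)


def load_culture_counts() -> pd.DataFrame:
    """Published per-sample γδ T-cell counts (×10⁶) over 21 days of rapid
    expansion culture, long format (sample_id, day, gd_count_millions)."""
    with resources.as_file(_data_path("rep_culture_counts.csv")) as p:
        return pd.read_csv(p)


def load_chemokine_mfi() -> pd.DataFrame:
    """Background-subtracted MFI of CXCR3/CXCR6/CCR5 surface staining on
    γδ T cells before (day 0) and after (day 21) expansion culture."""
    with resources.as_file(_data_path("chemokine_receptor_mfi.csv")) as p:
        return pd.read_csv(p)


def load_default_signatures() -> dict[str, GeneSignature]:
    """Synthetic stand-in signatures aligned with the simulator's default
    state programs (the published gene lists are third-party resources and
    are treated as user-supplied data)."""
    with resources.as_file(_data_path("synthetic_signatures.tsv")) as p:
        sets = read_signatures(p)
    sigs = {name: GeneSignature(name=name, genes=genes) for name, genes in sets.items()}
    return sigs


def default_innateness_reference() -> InnatenessReference:
    """Innateness reference built from the synthetic stand-in gene sets."""
    sets = load_default_signatures()
    return InnatenessReference(
        up_set=sets["innateness_up"].genes,
        down_set=sets["innateness_down"].genes,
    )


def default_state_signatures() -> dict[str, GeneSignature]:
    """One signature per simulated cell state (its program genes), used to
    map query clusters back onto the annotated states."""
    return {
        state: GeneSignature(name=state, genes=sorted(prog))
        for state, prog in DEFAULT_PROGRAMS.items()
    }
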