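"""uvrsig: tumor UV-response signature derivation and downstream analyses.

The package covers the full desk-scale workflow around a tumor-specific
UV-response expression signature: deriving the signature from annotated
single-cell data, scoring samples by single-sample enrichment,
predicting immunotherapy response with a nearest-centroid model,
meta-ranking CRISPR screens for immune-resistance genes, selecting hub
genes by multi-selector consensus, Cox/Kaplan–Meier risk modelling, and
consensus-clustering subtyping — all exercisable end-to-end on the
synthetic cohorts from :mod:`uvrsig.synthdata`.
"""

from importlib import resources

from . import (  # noqa: F401
    core,
    crispr,
    enrichment,
    ici_model,
    prognosis,
    signature,
    subtyping,
    synthdata,
)
from .core import (  # noqa: F401
    ExpressionMatrix,
    GeneSet,
    SignatureCollection,
    read_gmt,
    read_matrix,
    write_gmt,
    write_matrix,
)

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path-like handle to a packaged data file (e.g. ``uvr_sig.gmt``)."""
    return resources.files("uvrsig").joinpath("data", name)


def load_uvr_sig() -> GeneSet:
    """The published 38-gene tumor-specific UV-response signature."""
    with resources.as_file(packaged_data("uvr_sig.gmt")) as p:
        return read_gmt(p)["UVR.Sig"]


def load_hub_sig() -> GeneSet:
    """The published 7-gene hub subset of the UV-response signature."""
    with resources.as_file(packaged_data("uvr_sig.gmt")) as p:
        return read_gmt(p)["Hub-UVR.Sig"]
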