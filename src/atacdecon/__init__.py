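"""atacdecon: cell-type deconvolution of bulk chromatin-accessibility mixtures.

The pipeline, end to end: build a non-redundant peak atlas from reference
peak calls; quantile-normalize the reference intensity matrix and drop
sub-median features; call cell-type-specific peaks with an intersection-
union test and rank them by pi-value; sweep per-type marker counts to find
the signature matrix B with minimum condition number; solve m = B f per
mixture with SIMPLS, clipping negative coefficients and renormalizing to
proportions; and score the result with RMSE/PCC against known truth and a
Monte-Carlo Wasserstein goodness-of-fit p-value.
"""

from __future__ import annotations

import warnings

from .profiles import MixtureMatrix, ReferenceProfile, median_intensity_filter, quantile_normalize
from .ctsp import call_ctsps
from .signature import SignatureMatrix, build_signature
from .transform import TransformSpec
from .deconv import ProportionEstimate, estimate_proportions, proportions_frame
from .evaluate import evaluate_deconvolution

__version__ = "0.1.0"

__all__ = [
    "ReferenceProfile",
    "MixtureMatrix",
    "SignatureMatrix",
    "TransformSpec",
    "ProportionEstimate",
    "build_signature_from_reference",
    "deconvolve",
    "estimate_proportions",
    "proportions_frame",
    "evaluate_deconvolution",
]


def build_signature_from_reference(
    reference: ReferenceProfile,
    g: int = 50,
    G: int = 150,
    max_p: float = 0.05,
    median_filter: bool = True,
) -> SignatureMatrix:
    """Reference profile -> signature matrix (normalize, filter, CTSP, sweep)."""
    norm = quantile_normalize(reference)
    if median_filter:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = median_intensity_filter(norm)
    ctsps = call_ctsps(norm, max_p=max_p)
    return build_signature(ctsps, norm, g=g, G=G)


def deconvolve(
    reference: ReferenceProfile,
    mixtures: MixtureMatrix,
    g: int = 50,
    G: int = 150,
    max_p: float = 0.05,
    transform: TransformSpec | None = None,
    n_components: int | None = None,
):
    """Full pipeline: returns ``(SignatureMatrix, list[ProportionEstimate])``."""
    sig = build_signature_from_reference(reference, g=g, G=G, max_p=max_p)
    estimates = estimate_proportions(sig, mixtures, transform=transform, n_components=n_components)
    return sig, estimates
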