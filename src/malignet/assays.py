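"""Closed-form assay scores.

Small pure functions for quantitative wet-lab readouts: genome-editing
mutation frequency from a T7E1 cleavage assay, the immunohistochemistry
H-index, qRT-PCR fold change by the 2^-ddCt method, and caliper tumor
volume.
"""

from __future__ import annotations

import warnings

from .errors import InputError

__all__ = ["t7e1_mutation_frequency", "h_index", "fold_change_ddct", "tumor_volume"]


def t7e1_mutation_frequency(fraction_cleaved: float) -> float:
    """Mutation frequency (%) = 100 * (1 - sqrt(1 - fraction cleaved)).

    The cleaved fraction of a reannealed heteroduplex amplicon reflects
    the probability that a duplex pairs a mutant with a wild-type strand;
    inverting that gives the editing frequency.
    """
    if not 0 <= fraction_cleaved <= 1:
        raise InputError("fraction_cleaved must lie in [0, 1]")
    return 100.0 * (1.0 - (1.0 - fraction_cleaved) ** 0.5)


def h_index(weak: float, moderate: float, strong: float) -> float:
    """IHC Hirsch index: 1*weak% + 2*moderate% + 3*strong%, range [0, 300]."""
    for name, v in (("weak", weak), ("moderate", moderate), ("strong", strong)):
        if not 0 <= v <= 100:
            raise InputError(f"{name} percentage must lie in [0, 100]")
    if weak + moderate + strong > 100:
        raise InputError("staining percentages sum above 100")
    return 1.0 * weak + 2.0 * moderate + 3.0 * strong


def fold_change_ddct(delta_delta_ct: float) -> float:
    """qRT-PCR relative expression: 2 ** (-ddCt)."""
    return 2.0 ** (-delta_delta_ct)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume (mm^3): (length * width^2) / 2.

    Warns (rather than erroring) when width exceeds length: which caliper
    axis is "length" is a measurement convention.
    """
    if length < 0 or width < 0:
        raise InputError("length and width must be nonnegative")
    if width > length:
        warnings.warn("width exceeds length; check caliper axes", stacklevel=2)
    return length * width * width / 2.0
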