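"""Allele misassignment probability bounds for panel-based classification.

When a focal specimen's allele is classified by comparing it to a small
species panel, the allele can be attributed to the wrong species if the
panel sample happened not to reveal it in the true species. For a site
with allele frequency ``f`` in the parental species and a panel unique
read depth of ``urd`` independently sampled alleles, that event requires
all ``urd`` panel draws to carry the major allele and the focal draw to
carry the minor one:

    P(f, urd) = f**urd * (1 - f)

The frequency maximizing P is f_max = urd / (urd + 1), giving the
worst-case bound

    P_max(urd) = (urd / (urd + 1))**urd * (1 / (urd + 1))

which is strictly decreasing in urd (0.148, 0.105, 0.082 for urd = 2, 3,
4). These are upper bounds, not error rates: they are attained only if
every site segregates at exactly the worst-case frequency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["misassignment_prob", "worst_case_freq", "max_misassignment_prob"]


def _check_urd(urd) -> None:
    arr = np.asarray(urd)
    if np.any(arr < 1) or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("urd must be a positive integer (>= 1)")
    if np.any(arr != np.floor(arr)):
        raise ValueError("urd must be integral")


def misassignment_prob(f: float, urd: int):
    """Probability of assigning the focal allele to the wrong species.

    ``f`` is the allele frequency in the parental species, ``urd`` the
    species-specific unique read depth of the panel.
    """
    _check_urd(urd)
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequency must be in [0, 1]")
    out = f ** np.asarray(urd) * (1.0 - f)
    return out.item() if out.ndim == 0 else out


def worst_case_freq(urd: int):
    """Allele frequency maximizing the misassignment probability."""
    _check_urd(urd)
    urd = np.asarray(urd, dtype=float)
    out = urd / (urd + 1.0)
    return out.item() if out.ndim == 0 else out


def max_misassignment_prob(urd: int):
    """Worst-case misassignment probability at unique read depth ``urd``."""
    f = worst_case_freq(urd)
    return misassignment_prob(f, urd)
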