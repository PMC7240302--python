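"""The combinatorial transcription-factor code of T4/T5 subtypes.

Each of the four subtypes is specified by a minimal three-bit code: a
Dac/Ab-class flag (subtypes a, b), a mutually exclusive Omb/Pros-class flag
(subtypes c, d; Omb represses Dac, so exactly one class flag is ever set),
and a Grain flag (subtypes b, c):

=========  ========  ========  =====
subtype    Dac/Ab    Omb/Pros  Grain
=========  ========  ========  =====
a          +         -         -
b          +         -         +
c          -         +         +
d          -         +         -
=========  ========  ========  =====

Gain of Grain converts a -> b and d -> c; loss of Grain converts b -> a and
c -> d. The class flags are never changed by Grain perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TFCode",
    "InvalidCodeError",
    "decode_tf_code",
    "encode_subtype",
    "perturb_code",
    "PERTURBATION_MODES",
]

PERTURBATION_MODES = ("none", "overexpression", "knockdown")


class InvalidCodeError(ValueError):
    """Raised for codes that violate the class-flag exclusivity invariant."""


@dataclass(frozen=True)
class TFCode:
    """Boolean triple (Dac/Ab class, Omb/Pros class, Grain).

    Exactly one of ``class_ab`` and ``class_cd`` must be set.
    """

    class_ab: bool
    class_cd: bool
    grain: bool

    def __post_init__(self) -> None:
        if self.class_ab == self.class_cd:
            raise InvalidCodeError(
                "exactly one of class_ab / class_cd must be set "
                f"(got class_ab={self.class_ab}, class_cd={self.class_cd})"
            )


_DECODE = {
    (True, False): "a",
    (True, True): "b",
    (False, True): "c",
    (False, False): "d",
}


def decode_tf_code(code: TFCode) -> str:
    """Map a TF code to its subtype: (ab,-)->a, (ab,+)->b, (cd,+)->c, (cd,-)->d."""
    if not isinstance(code, TFCode):
        raise TypeError("decode_tf_code expects a TFCode")
    return _DECODE[(code.class_ab, code.grain)]


def encode_subtype(subtype: str) -> TFCode:
    """Inverse of :func:`decode_tf_code` on {a, b, c, d}."""
    table = {
        "a": TFCode(True, False, False),
        "b": TFCode(True, False, True),
        "c": TFCode(False, True, True),
        "d": TFCode(False, True, False),
    }
    try:
        return table[subtype]
    except KeyError:
        raise ValueError(f"unknown subtype: {subtype!r}") from None


def perturb_code(code: TFCode, mode: str) -> TFCode:
    """Apply a Grain perturbation to a code.

    ``overexpression`` sets the Grain flag, ``knockdown`` clears it,
    ``none`` is the identity. Class flags never change, so the image of
    overexpression is {b, c} and of knockdown {a, d}.
    """
    if not isinstance(code, TFCode):
        raise TypeError("perturb_code expects a TFCode")
    if mode == "none":
        return code
    if mode == "overexpression":
        return TFCode(code.class_ab, code.class_cd, True)
    if mode == "knockdown":
        return TFCode(code.class_ab, code.class_cd, False)
    raise ValueError(f"unknown perturbation mode: {mode!r}")
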