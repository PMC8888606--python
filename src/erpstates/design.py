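"""The divided-visual-field condition design.

Eight conditions code what was shown in the left/right visual field (LVF/RVF):
four unilateral (one angry AN or happy HA face plus a checkerboard) and four
bilateral (two faces).  Condition codes read ``<LVF stimulus>-<RVF stimulus>``
for bilateral trials and ``<emotion>-<side>`` for unilateral trials.
"""

from __future__ import annotations

UNILATERAL = ("AN-LVF", "AN-RVF", "HA-LVF", "HA-RVF")
BILATERAL = ("AN-AN", "HA-HA", "AN-HA", "HA-AN")
CONDITIONS = UNILATERAL + BILATERAL

#: Emotion and side factors of the unilateral 2 x 2 sub-design.
EMOTION_OF = {"AN-LVF": "AN", "AN-RVF": "AN", "HA-LVF": "HA", "HA-RVF": "HA"}
SIDE_OF = {"AN-LVF": "LVF", "AN-RVF": "RVF", "HA-LVF": "LVF", "HA-RVF": "RVF"}

LVF_CONDITIONS = ("AN-LVF", "HA-LVF")
RVF_CONDITIONS = ("AN-RVF", "HA-RVF")

#: Five-level valence families: every condition in which a face of the given
#: valence appears somewhere in the display.  The mixed bilateral conditions
#: (AN-HA, HA-AN) belong to both families and each family is analysed
#: independently.
VALENCE_FAMILIES = {
    "negative": ("AN-LVF", "AN-RVF", "AN-AN", "AN-HA", "HA-AN"),
    "positive": ("HA-LVF", "HA-RVF", "HA-HA", "HA-AN", "AN-HA"),
}


def presentation_of(condition: str) -> str:
    """"unilateral" or "bilateral" for a condition code."""
    if condition in UNILATERAL:
        return "unilateral"
    if condition in BILATERAL:
        return "bilateral"
    raise KeyError(f"unknown condition code {condition!r}")
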