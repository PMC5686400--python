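"""Bundled example strings.

The four 60-character strings span the complexity range from highly
repetitive to essentially random: a random letter sequence, an excerpt from
*Green Eggs and Ham* (Dr. Seuss; famously repetitive prose), an excerpt from
*Dracula* (Bram Stoker; ordinary English), and the word "redrum" repeated
ten times. All are lower case with spaces and punctuation removed, so the
fundamental alphabet is plain letters. ``COATCOATCORNCORN`` illustrates the
difference between pathway complexity (the shared "CO" is built once) and
the recursive-tree variant (each branch rebuilds its own "CO").
"""

BANANA = "banana"

#: 60-character random letter sequence
RANDOM60 = "anpncsaveuoaklkgobqfdfoqtyilrzausbcbsxfclanbipcwizlmajbualbs"

#: 60 characters of Green Eggs and Ham
SEUSS60 = "iamsamiamsamsamiamthatsamiamthatsamiamidonotlikethatsamiamdo"

#: 60 characters of Dracula
DRACULA60 = "myfriendwelcometothecarpathiansiamanxiouslyexpectingyousleep"

#: "redrum" repeated ten times (60 characters)
REDRUM60 = "redrum" * 10

#: paired duplicated words sharing an internal bigram
COATCORN = "COATCOATCORNCORN"

ALL_60CHAR = {
    "random60": RANDOM60,
    "seuss60": SEUSS60,
    "dracula60": DRACULA60,
    "redrum60": REDRUM60,
}

NAMED = {"banana": BANANA, "coatcorn": COATCORN, **ALL_60CHAR}
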