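"""Regenerate the bundled reference FASTA.

The bundled reference uses the standard 16,569-bp human mtDNA coordinate
frame and gene annotation.  The base content is a seeded placeholder
(the true reference sequence cannot be redistributed from this build
environment), with a set of well-known landmark positions pinned to their
real values so that standard notation examples (C-stretch, AC repeat,
9-bp repeat, HVS-I poly-C region) behave as documented.

Run from the repository root:  python scripts/make_reference_fasta.py
"""

from pathlib import Path

import numpy as np

LENGTH = 16569
SEED = 12345

# Landmark positions pinned to their true bases.
PATCH: dict[int, str] = {
    73: "A", 150: "C", 152: "T", 263: "A", 279: "T", 373: "A", 489: "T",
    3010: "G", 5178: "C", 8701: "A", 10398: "A", 10400: "C", 12705: "C",
    14783: "T", 15043: "G",
    16172: "T", 16182: "A", 16183: "A",
    16223: "C", 16290: "C", 16311: "T", 16319: "G", 16362: "T", 16519: "T",
}
# 303-315 poly-C tract (CCCCCCCTCCCCC), 515-522 AC repeat,
# 8272-8289 tandem 9-bp repeat (CCCCCTCTA x2), 16184-16193 HVS-I poly-C.
for i, b in enumerate("CCCCCCCTCCCCC"):
    PATCH[303 + i] = b
for i, b in enumerate("ACACACAC"):
    PATCH[515 + i] = b
for i, b in enumerate("CCCCCTCTACCCCCTCTA"):
    PATCH[8272 + i] = b
for i, b in enumerate("CCCCCTCCCC"):
    PATCH[16184 + i] = b


def main() -> None:
    rng = np.random.default_rng(SEED)
    bases = rng.choice(list("ACGT"), size=LENGTH)
    seq = list("".join(bases))
    for pos, base in PATCH.items():
        seq[pos - 1] = base
    out = Path(__file__).resolve().parents[1] / "src/mtphylogeo/data/reference.fasta"
    with open(out, "w") as fh:
        fh.write(">chrM standard 16569-bp mtDNA coordinate frame (placeholder bases, pinned landmarks)\n")
        s = "".join(seq)
        for i in range(0, LENGTH, 70):
            fh.write(s[i : i + 70] + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
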