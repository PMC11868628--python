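#!/usr/bin/env python
"""Resolve the undocumented fully-connected head widths of the binary
classifier.

The published description fixes the encoder (3->16 initial conv, channel
doubling capped at 256 over five poolings, 16x16x256 terminal), the
bottleneck contract (progressive channel narrowing with per-channel
attention down to 16x16x8), the head layout (flatten, FC+dropout twice,
2-way softmax) and the total trainable parameter count (1,718,770) — but
not the two FC widths nor the bottleneck's internal details. This script
enumerates a small lattice of bottleneck designs and all integer width
pairs, keeping the combinations whose parameter total matches exactly.

The package's frozen choice is the halving schedule 256->128->64->32->16->8
with 3x3 narrowing convolutions, a post-conv dense attention gate
(GAP -> dense C->C -> sigmoid), and head widths (144, 176).

Run:  python scripts/resolve_head_widths.py
"""

from __future__ import annotations

TARGET = 1_718_770
FLAT = 16 * 16 * 8          # flattened bottleneck output


def conv_params(cin: int, cout: int, k: int) -> int:
    return k * k * cin * cout + cout


def encoder_params() -> int:
    chans = [16, 32, 64, 128, 256, 256]
    total = conv_params(3, 16, 3)
    for cin, cout in zip(chans[:-1], chans[1:]):
        total += conv_params(cin, cout, 3)
    return total


def se_attention(channels: int, reduction: int) -> int:
    hidden = max(channels // reduction, 1)
    return channels * hidden + hidden + hidden * channels + channels


def dense_attention(channels: int) -> int:
    return channels * channels + channels


SCHEDULES = {
    "halve": [256, 128, 64, 32, 16, 8],
    "quarter": [256, 64, 16, 8],
    "steep": [256, 128, 32, 8],
    "direct": [256, 8],
}
ATTENTIONS = {
    "dense": dense_attention,
    **{f"se{r}": (lambda r: (lambda c: se_attention(c, r)))(r)
       for r in (2, 4, 8, 16)},
}


def bottleneck_params(schedule, kernel, attention, att_position) -> int:
    total = 0
    for cin, cout in zip(schedule[:-1], schedule[1:]):
        total += conv_params(cin, cout, kernel)
        total += attention(cin if att_position == "pre" else cout)
    return total


def head_widths_for(budget: int):
    """Integer (w1, w2) with FLAT*w1+w1 + w1*w2+w2 + 2*w2+2 == budget."""
    for w1 in range(16, 1025):
        rem = budget - (FLAT * w1 + w1) - 2
        if rem <= 0:
            return
        if rem % (w1 + 3) == 0:
            w2 = rem // (w1 + 3)
            if 8 <= w2 <= 1024:
                yield w1, w2


def main() -> None:
    enc = encoder_params()
    print(f"encoder parameters: {enc}")
    solutions = []
    for sname, schedule in SCHEDULES.items():
        for kernel in (1, 3):
            for aname, att in ATTENTIONS.items():
                for pos in ("pre", "post"):
                    fixed = enc + bottleneck_params(schedule, kernel,
                                                    att, pos)
                    for w1, w2 in head_widths_for(TARGET - fixed):
                        solutions.append((sname, kernel, aname, pos,
                                          w1, w2))
    print(f"{len(solutions)} exact solutions for a total of {TARGET}:")
    for s in sorted(solutions,
                    key=lambda s: -((s[4] % 8 == 0) + (s[5] % 8 == 0))):
        print(f"  schedule={s[0]:8s} conv={s[1]}x{s[1]} attention={s[2]:6s}"
              f" ({s[3]:4s}) widths=({s[4]}, {s[5]})")
    chosen = ("halve", 3, "dense", "post", 144, 176)
    assert chosen in solutions
    print(f"\nfrozen in the package: schedule=halve, 3x3 narrowing convs, "
          f"post-conv dense attention gate, head widths (144, 176)")


if __name__ == "__main__":
    main()
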