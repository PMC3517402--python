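"""Built-in example models.

Three curated networks exercise every part of the toolchain:

``toy`` / ``toy-fast`` / ``toy-slow``
    Three species A, B, C: A is activated by C and inhibited by B, B is
    activated by A, C is activated by A or B.  All transition rates are 1
    except the rate of the transition [ABC]=[001] -> [000] (inactivation
    of C with A and B absent), exposed as the parameter ``$escape``
    (fast: 10, slow: 1e-5).  The transition graph is a 4-state cycle
    {[111],[011],[001],[101]} draining through [001] into the fixed point
    [000].

``p53``
    p53 response to DNA damage with a two-level p53 encoded by the
    auxiliary-node pattern (``p53`` = level >= 1, ``p53_h`` = level 2).
    High p53 drives cytoplasmic Mdm2 (Mdm2C); Mdm2C feeds nuclear Mdm2
    (Mdm2N), which also enters at a basal rate when neither p53 nor
    damage opposes it; Mdm2N degrades p53; DNA damage (Dam) destabilizes
    Mdm2N; high p53 promotes damage repair.  The logical rules are a
    reconstruction from the published narrative of the source model,
    validated structurally: the transition graph restricted to states
    reachable from consistent levels has the single fixed point
    [p53 Mdm2C Mdm2N Dam] = [0010] and two cycles.

``cellcycle``
    The 10-node Boolean model of the mammalian cell cycle (CycD, Rb,
    E2F, CycE, CycA, p27, Cdc20, Cdh1, UbcH10, CycB) with the published
    logical rules; CycD is a constant input representing growth factors.
    Transitions use two rates, slow (1) and fast (10): the
    phosphorylation-controlled regulators Rb, E2F, p27 and Cdh1 switch
    fast, while species governed by synthesis and degradation (the
    cyclins, Cdc20, UbcH10) switch slowly.

``random-<k>-node``
    Seeded random rate-annotated networks for property tests: each
    node's rates are random threshold expressions over one to three
    randomly chosen regulators with rates drawn from a small grid.

Every fixture returns ``(model_text, config_text)`` strings in the
package's model/config dialect; parse them with
:func:`bkmc.parse_model` / :func:`bkmc.parse_config`.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("toy", "toy-fast", "toy-slow", "p53", "cellcycle", "random-k-node")

_TOY_BND = """\
# Single-cycle toy network: A activated by C, inhibited by B;
# B activated by A; C activated by A or B.
node A {
  rate_up = (C & !B) ? 1.0 : 0.0;
  rate_down = (C & !B) ? 0.0 : 1.0;
}
node B {
  rate_up = A ? 1.0 : 0.0;
  rate_down = A ? 0.0 : 1.0;
}
node C {
  rate_up = (A | B) ? 1.0 : 0.0;
  rate_down = (A | B) ? 0.0 : $escape;
}
"""

_TOY_FAST_CFG = """\
$escape = 10;
timetick = 0.1;
max_time = 4;
sample_count = 50000;
statdist_traj_count = 1000;
statdist_cluster_threshold = 0.9;
seed = 0;
"""

_TOY_SLOW_CFG = """\
$escape = 1e-5;
timetick = 0.1;
max_time = 10;
sample_count = 50000;
statdist_traj_count = 1000;
statdist_cluster_threshold = 0.9;
seed = 0;
"""

# Reconstructed two-level p53 / Mdm2 / DNA-damage network.  p53 and p53_h
# follow the auxiliary-node multi-level pattern: p53_h can only rise while
# p53 is on, and p53 cannot fall while p53_h is on.
_P53_BND = """\
node p53 {
  rate_up = !Mdm2N ? 1.0 : 0.0;
  rate_down = (!Mdm2N | p53_h) ? 0.0 : 1.0;
}
node p53_h {
  rate_up = (p53 & !Mdm2N) ? 1.0 : 0.0;
  rate_down = Mdm2N ? 1.0 : 0.0;
}
node Mdm2C {
  rate_up = p53_h ? 1.0 : 0.0;
  rate_down = p53_h ? 0.0 : 1.0;
}
node Mdm2N {
  logic = Mdm2C | (!p53 & !Dam);
  rate_up = @logic ? 1.0 : 0.0;
  rate_down = @logic ? 0.0 : 1.0;
}
node Dam {
  rate_up = 0.0;
  rate_down = p53_h ? 1.0 : 0.0;
}
"""

# Initial condition [p53 Mdm2C Mdm2N Dam] = [0*11]: damage present,
# nuclear Mdm2 on, no p53; cytoplasmic Mdm2 random.
_P53_CFG = """\
timetick = 0.1;
max_time = 30;
sample_count = 20000;
statdist_traj_count = 500;
statdist_cluster_threshold = 0.9;
seed = 0;
p53.istate = 0;
p53_h.istate = 0;
Mdm2N.istate = 1;
Dam.istate = 1;
"""

# Published 10-node mammalian cell-cycle logic; CycD (growth factors) is a
# self-sustaining input.  @logic is the node's Boolean target value.
_CELLCYCLE_BND = """\
node CycD {
  logic = CycD;
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
node Rb {
  logic = (!CycD & !CycE & !CycA & !CycB) | (p27 & !CycD & !CycB);
  rate_up = @logic ? $rate_fast : 0.0;
  rate_down = @logic ? 0.0 : $rate_fast;
}
node E2F {
  logic = (!Rb & !CycA & !CycB) | (p27 & !Rb & !CycB);
  rate_up = @logic ? $rate_fast : 0.0;
  rate_down = @logic ? 0.0 : $rate_fast;
}
node CycE {
  logic = E2F & !Rb;
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
node CycA {
  logic = (E2F & !Rb & !Cdc20 & !(Cdh1 & UbcH10)) | (CycA & !Rb & !Cdc20 & !(Cdh1 & UbcH10));
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
node p27 {
  logic = (!CycD & !CycE & !CycA & !CycB) | (p27 & !(CycE & CycA) & !CycB & !CycD);
  rate_up = @logic ? $rate_fast : 0.0;
  rate_down = @logic ? 0.0 : $rate_fast;
}
node Cdc20 {
  logic = CycB;
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
node Cdh1 {
  logic = (!CycA & !CycB) | Cdc20 | (p27 & !CycB);
  rate_up = @logic ? $rate_fast : 0.0;
  rate_down = @logic ? 0.0 : $rate_fast;
}
node UbcH10 {
  logic = !Cdh1 | (Cdh1 & UbcH10 & (Cdc20 | CycA | CycB));
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
node CycB {
  logic = !Cdc20 & !Cdh1;
  rate_up = @logic ? $rate_slow : 0.0;
  rate_down = @logic ? 0.0 : $rate_slow;
}
"""

# G1 state in the presence of growth factors: CycD, Rb, p27, Cdh1 on.
_CELLCYCLE_CFG = """\
$rate_slow = 1;
$rate_fast = 10;
timetick = 0.5;
max_time = 100;
sample_count = 5000;
statdist_traj_count = 500;
statdist_cluster_threshold = 0.9;
seed = 0;
CycD.istate = 1;
Rb.istate = 1;
E2F.istate = 0;
CycE.istate = 0;
CycA.istate = 0;
p27.istate = 1;
Cdc20.istate = 0;
Cdh1.istate = 1;
UbcH10.istate = 0;
CycB.istate = 0;
"""


def _random_expr(names: list[str], rng: np.random.Generator) -> str:
    k = int(rng.integers(1, min(3, len(names)) + 1))
    picks = rng.choice(len(names), size=k, replace=False)
    lits = [("!" if rng.random() < 0.5 else "") + names[i] for i in picks]
    op = " & " if rng.random() < 0.5 else " | "
    return "(" + op.join(lits) + ")"


_RATE_GRID = (0.0, 0.3, 1.0, 3.0)


def _random_model_text(n: int, seed: int) -> str:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0xA5))))
    names = [f"N{i}" for i in range(n)]
    blocks = []
    for name in names:
        up_t, up_f = rng.choice(_RATE_GRID, size=2)
        dn_t, dn_f = rng.choice(_RATE_GRID, size=2)
        blocks.append(
            f"node {name} {{\n"
            f"  rate_up = {_random_expr(names, rng)} ? {up_t} : {up_f};\n"
            f"  rate_down = {_random_expr(names, rng)} ? {dn_t} : {dn_f};\n"
            f"}}"
        )
    return "\n".join(blocks) + "\n"


def make_fixture(name: str, seed: int = 0) -> tuple[str, str]:
    """Return ``(model_text, config_text)`` for a named fixture.

    ``toy`` is an alias for ``toy-fast``; ``random-<k>-node`` takes the
    node count from the name and varies with ``seed`` (same seed, same
    text).
    """
    if name in ("toy", "toy-fast"):
        return _TOY_BND, _TOY_FAST_CFG
    if name == "toy-slow":
        return _TOY_BND, _TOY_SLOW_CFG
    if name == "p53":
        return _P53_BND, _P53_CFG
    if name == "cellcycle":
        return _CELLCYCLE_BND, _CELLCYCLE_CFG
    m = re.fullmatch(r"random-(\d+)-node", name)
    if m:
        n = int(m.group(1))
        if not 1 <= n <= 64:
            raise ValueError(f"random fixture size {n} out of range 1..64")
        cfg = (
            "timetick = 0.5;\nmax_time = 5;\nsample_count = 1000;\n"
            f"seed = {seed};\n"
        )
        return _random_model_text(n, seed), cfg
    raise ValueError(
        f"unknown fixture {name!r}; expected one of {', '.join(FIXTURE_NAMES)}"
    )
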