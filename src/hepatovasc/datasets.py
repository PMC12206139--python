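"""Bundled reference tables.

``load_separation_morphometry`` returns per-mouse sinusoid morphometry
(density, cylinder-model radius in um, tortuosity) measured before and
after vessel-sinusoid separation in normal and early-stage NASH mice from
a three-mouse liver OR-PAM study.  It is the canonical input for
:func:`hepatovasc.morphometry.relative_change_table` and for validating the
pre/post-separation comparison arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_separation_morphometry", "separation_pairs"]


def load_separation_morphometry() -> pd.DataFrame:
    """Long-format table: stage, mouse, separation state, three metrics."""
    ref = resources.files("hepatovasc") / "data" / "separation_morphometry.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def separation_pairs(stage: str, metric: str,
                     states: tuple[str, str] = ("unseparated", "separated"),
                     df: pd.DataFrame | None = None) -> list[tuple[float, float]]:
    """Per-mouse (a, b) metric pairs for a stage, ordered by mouse id.

    ``states`` picks which two rows form the pair; pass two stages with the
    same state via ``stage=None``-style filtering is not supported — use
    :func:`cross_stage_pairs` for stage-to-stage comparisons.
    """
    df = load_separation_morphometry() if df is None else df
    sub = df[df["stage"] == stage]
    pairs = []
    for mouse, grp in sub.groupby("mouse"):
        a = float(grp.loc[grp["separation"] == states[0], metric].iloc[0])
        b = float(grp.loc[grp["separation"] == states[1], metric].iloc[0])
        pairs.append((a, b))
    return pairs


def cross_stage_pairs(stage_a: str, stage_b: str, metric: str,
                      separation: str = "separated",
                      df: pd.DataFrame | None = None) -> list[tuple[float, float]]:
    """Per-mouse (stage_a, stage_b) pairs at a fixed separation state."""
    df = load_separation_morphometry() if df is None else df
    sub = df[df["separation"] == separation]
    a = sub[sub["stage"] == stage_a].set_index("mouse")[metric]
    b = sub[sub["stage"] == stage_b].set_index("mouse")[metric]
    return [(float(a[m]), float(b[m])) for m in sorted(a.index)]
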