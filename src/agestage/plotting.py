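"""Minimal line plots of schedules and projections (optional exports)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .lifetable import Schedule
from .projection import ProjectionResult
from .cohort import STAGES


def plot_schedule(schedule: Schedule, path: str | Path, title: str = "") -> Path:
    """l_x, m_x and l_x m_x against age, one panel."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax2 = ax.twinx()
    ax.plot(schedule.ages, schedule.l_x, color="tab:blue", label="l_x")
    ax2.plot(schedule.ages, schedule.m_x, color="tab:red", label="m_x")
    ax2.plot(schedule.ages, schedule.lm_x, color="tab:green", label="l_x m_x")
    ax.set_xlabel("age (d)")
    ax.set_ylabel("survivorship l_x")
    ax2.set_ylabel("fecundity (eggs/day)")
    if title:
        ax.set_title(title)
    handles = ax.get_lines() + ax2.get_lines()
    ax.legend(handles, [h.get_label() for h in handles], loc="upper right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_projection(result: ProjectionResult, path: str | Path, log10: bool = True,
                    title: str = "") -> Path:
    """Per-stage and total population trajectories."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, stage in enumerate(STAGES):
        ax.plot(result.days, result.counts[:, j], label=stage)
    ax.plot(result.days, result.total, "k--", label="total")
    if log10:
        ax.set_yscale("log")
    ax.set_xlabel("day")
    ax.set_ylabel("expected individuals")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
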