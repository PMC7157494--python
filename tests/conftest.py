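import numpy as np
import pandas as pd
import pytest

from mrtmod import DesignConfig, default_truths, simulate_trial


@pytest.fixture(scope="session")
def small_config():
    return DesignConfig(n_participants=60, n_weeks=8, seed=42)


@pytest.fixture(scope="session")
def small_daily(small_config):
    """Complete (no-missingness) daily panel for a small trial."""
    return simulate_trial(small_config, default_truths(), missingness={})


@pytest.fixture(scope="session")
def medium_daily():
    """Complete daily panel at a moderate size for distributional checks."""
    cfg = DesignConfig(n_participants=400, n_weeks=26, seed=7)
    return simulate_trial(cfg, default_truths(), missingness={})


def constant_daily_panel(n_participants, n_weeks, mood=7.0, steps=9.0,
                         sleep=360.0, arm="mood"):
    """Structurally complete daily panel with constant values (fast to build)."""
    n_days = (n_weeks + 1) * 7
    pid = np.repeat(np.arange(1, n_participants + 1), n_days)
    study_day = np.tile(np.arange(-6, n_weeks * 7 + 1), n_participants)
    week = np.ceil(study_day / 7.0).astype(int)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "study_day": study_day,
            "week_index": week,
            "arm": np.where(week == 0, "none", arm),
            "delivered": False,
            "message_id": None,
            "mood": float(mood),
            "steps": float(steps),
            "sleep_minutes": float(sleep),
        }
    )
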