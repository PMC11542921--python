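"""Electrode-usage statistics and dictionary-subsampling analysis.

The greedy encoder concentrates stimulation on a subset of electrodes; this
module quantifies that concentration and asks how much reconstruction error
grows when the dictionary is restricted to the most frequently used fraction
of electrodes — the data-driven hardware-efficiency question for an implant
that could power down rarely used channels.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bounds import relaxed_joint
from .greedy import GreedyWorkspace, StimulationSequence, run_greedy
from .synthetic import ReconstructionFilter, StimDictionary

__all__ = ["electrode_usage", "rank_electrodes", "subsampling_curve"]


def electrode_usage(sequences: Iterable[StimulationSequence],
                    n_electrodes: int) -> np.ndarray:
    """Per-electrode stimulation frequency across sequences (sums to 1 if any picks)."""
    counts = np.zeros(n_electrodes)
    for seq in sequences:
        elec = seq.picks["electrode_id"].to_numpy()
        elec = elec[elec >= 0]
        if elec.size:
            counts += np.bincount(elec, minlength=n_electrodes)
    total = counts.sum()
    return counts / total if total > 0 else counts


def rank_electrodes(usage: np.ndarray) -> np.ndarray:
    """Electrode ids sorted by decreasing usage; ties resolved by lower id."""
    return np.lexsort((np.arange(usage.size), -usage))


def subsampling_curve(filters: ReconstructionFilter, dictionary: StimDictionary,
                      train_targets: Sequence, eval_targets: Sequence,
                      fractions: Sequence[float] | None = None, seed=None, *,
                      T_max: int = 10_000,
                      refractory_params: tuple[float, int] = (0.1, 100),
                      ) -> pd.DataFrame:
    """Greedy error and relaxed lower bound vs fraction of electrodes kept.

    Electrodes are ranked by stimulation frequency over greedy runs on the
    training targets; for each fraction the dictionary is restricted to the
    top-ranked electrodes (plus the null element) and both the greedy expected
    error and the convex lower bound are re-evaluated on the held-out targets.
    Train and evaluation targets must be disjoint collections.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    train_keys = {t.pixels.tobytes() for t in train_targets}
    if any(t.pixels.tobytes() in train_keys for t in eval_targets):
        raise ValueError("train and eval target sets must be disjoint")

    n_elec = dictionary.electrode_positions.shape[0]
    ws = GreedyWorkspace(filters, dictionary)
    train_seqs = [run_greedy(t, filters, dictionary, T_max=T_max,
                             refractory_params=refractory_params, workspace=ws)
                  for t in train_targets]
    usage = electrode_usage(train_seqs, n_elec)
    ranked = rank_electrodes(usage)

    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n_keep = int(np.ceil(frac * n_elec))
        keep = ranked[:n_keep]
        sub = dictionary if n_keep == n_elec else dictionary.restrict_to_electrodes(keep)
        sub_ws = ws if sub is dictionary else GreedyWorkspace(filters, sub)
        greedy_errs, bound_errs = [], []
        for t in eval_targets:
            seq = run_greedy(t, filters, sub, T_max=T_max,
                             refractory_params=refractory_params, workspace=sub_ws)
            greedy_errs.append(seq.error.relative_mse)
            bound_errs.append(relaxed_joint(t, filters, sub).relative_objective)
        rows.append((float(frac), n_keep, float(np.mean(greedy_errs)),
                     float(np.mean(bound_errs))))
    return pd.DataFrame(rows, columns=["fraction", "n_electrodes",
                                       "greedy_error", "relaxed_bound"])
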