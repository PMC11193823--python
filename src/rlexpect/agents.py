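"""State updates, response rules, likelihoods and choice simulation.

All model variants share a Rescorla–Wagner core: the chosen stimulus's
expected value moves toward the binary reward by a learning rate that may
differ for positive (gain) and negative (loss) prediction errors,

    Q <- Q + alpha_gain * (r - Q)   if r - Q > 0
    Q <- Q + alpha_loss * (r - Q)   if r - Q < 0

with Q in [0, 1] and r in {0, 1}.  The response rule maps the two Q-values of
the presented pair to a choice probability; the conventions differ per family
(inverse gain divides Q by beta, inverse temperature multiplies, the ES rule
adds irreducible noise, the RLf-CK rule adds a choice-kernel term).

The per-trial operation order is: (1) choice probability from the current
state, (2) reward observed, (3) initial-bias injection on a pair's first trial
(ES only), (4) Rescorla–Wagner update of the chosen stimulus, (5) forgetting
decay of all six Q-values (ES/RLf-CK), (6) choice-kernel update (RLf-CK).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .families import (
    INVERSE_GAIN,
    KERNEL_SOFTMAX,
    NOISY_SOFTMAX,
    SOFTMAX,
    get_family,
)
from .params import params_to_array
from .task import TaskDesign, sample_feedback

#: inverse-gain beta is clamped at this floor before dividing
BETA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# elementary update operations
# ---------------------------------------------------------------------------

def dual_rate_update(q, r, alpha_gain, alpha_loss):
    """One Rescorla–Wagner step with separate gain/loss learning rates."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q={q} outside [0, 1]")
    if r not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r}")
    if not (0.0 <= alpha_gain <= 1.0 and 0.0 <= alpha_loss <= 1.0):
        raise ValueError("learning rates must lie in [0, 1]")
    pe = r - q
    alpha = alpha_gain if pe > 0 else alpha_loss
    return q + alpha * pe


def forget_decay(q_vector, phi):
    """Decay all stimulus values toward the initial value 0: Q <- (1 - phi) Q."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi={phi} outside [0, 1]")
    return np.asarray(q_vector, dtype=float) * (1.0 - phi)


def ck_update(ck_pair, chosen_index, alpha_ck):
    """Choice-kernel step: chosen value moves toward 1, unchosen toward 0."""
    ck = np.asarray(ck_pair, dtype=float)
    if ck.shape != (2,):
        raise ValueError("ck_pair must hold the two presented stimuli's values")
    if np.any((ck < 0) | (ck > 1)):
        raise ValueError("choice-kernel values must lie in [0, 1]")
    if not 0.0 <= alpha_ck <= 1.0:
        raise ValueError(f"alpha_ck={alpha_ck} outside [0, 1]")
    if chosen_index not in (0, 1):
        raise ValueError("chosen_index must be 0 or 1")
    out = ck.copy()
    out[chosen_index] += alpha_ck * (1.0 - out[chosen_index])
    other = 1 - chosen_index
    out[other] += alpha_ck * (0.0 - out[other])
    return out


# ---------------------------------------------------------------------------
# response rules
# ---------------------------------------------------------------------------

def choice_prob_inverse_gain(qA, qB, beta):
    """softmax(Q/beta): larger beta flattens the choice probability.

    Returns exactly 0.5 whenever qA == qB; beta is clamped at ``BETA_FLOOR``
    from below so the rule is defined for beta = 0.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if qA == qB:
        return 0.5
    z = (qA - qB) / max(beta, BETA_FLOOR)
    return float(expit(z))


def choice_prob_softmax(qA, qB, beta):
    """softmax(Q * beta), the inverse-temperature convention (beta in [0, 20])."""
    if not 0.0 <= beta <= 20.0:
        raise ValueError("beta must lie in [0, 20]")
    return float(expit(beta * (qA - qB)))


def choice_prob_noisy(qA, qB, beta, xi):
    """ES rule: (1 - xi) * softmax(Q * beta) + xi / 2."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return (1.0 - xi) * choice_prob_softmax(qA, qB, beta) + xi / 2.0


def choice_prob_ck(qA, qB, ckA, ckB, beta, tau):
    """RLf-CK rule: softmax over Q * beta + CK * tau."""
    if not 0.0 <= beta <= 20.0:
        raise ValueError("beta must lie in [0, 20]")
    if not -5.0 <= tau <= 5.0:
        raise ValueError("tau must lie in [-5, 5]")
    for name, v in (("ckA", ckA), ("ckB", ckB)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    z = beta * (qA - qB) + tau * (ckA - ckB)
    return float(expit(z))


# ---------------------------------------------------------------------------
# packed trial arrays and the vectorized likelihood core
# ---------------------------------------------------------------------------

@dataclass
class PackedTrials:
    """Trial arrays aligned for a vectorized forward pass over subjects.

    Arrays are (n_subjects, T_max); ``valid`` masks padding for subjects with
    fewer responded trials.  Stimuli are recoded to 0-based indices into the
    design's stimulus tuple.
    """

    subject_ids: np.ndarray
    groups: np.ndarray
    chosen: np.ndarray
    other: np.ndarray
    reward: np.ndarray
    first_of_pair: np.ndarray
    valid: np.ndarray
    n_stimuli: int

    @property
    def n_subjects(self) -> int:
        return self.chosen.shape[0]

    @property
    def n_trials(self) -> int:
        """Total number of (valid) trials across subjects."""
        return int(self.valid.sum())


def pack_trials(table: pd.DataFrame, design: TaskDesign) -> PackedTrials:
    """Validate a long-format trial table and pack it for the likelihood core."""
    required = {"subject_id", "trial", "pair", "choice", "reward"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table misses columns {sorted(missing)}")
    stim_index = {s: i for i, s in enumerate(design.stimuli)}
    partner = {}
    for p in design.pairs:
        partner[p.stim_better] = p.stim_worse
        partner[p.stim_worse] = p.stim_better

    subjects = list(pd.unique(table["subject_id"]))
    n = len(subjects)
    t_max = int(table.groupby("subject_id").size().max()) if n else 0
    chosen = np.zeros((n, t_max), dtype=np.int64)
    other = np.zeros((n, t_max), dtype=np.int64)
    reward = np.zeros((n, t_max), dtype=float)
    first = np.zeros((n, t_max), dtype=bool)
    valid = np.zeros((n, t_max), dtype=bool)
    groups = np.zeros(n, dtype=np.int64)

    for si, sid in enumerate(subjects):
        sub = table[table["subject_id"] == sid]
        trials = sub["trial"].to_numpy()
        if np.any(np.diff(trials) <= 0):
            raise ValueError(f"trials of subject {sid!r} are not strictly increasing")
        seen_pairs = set()
        if "group" in sub.columns:
            groups[si] = int(sub["group"].iloc[0])
        for ti, row in enumerate(sub.itertuples(index=False)):
            pair = design.pair(int(row.pair))
            c = int(row.choice)
            if c not in pair.stimuli:
                raise ValueError(
                    f"subject {sid!r} trial {row.trial}: choice {c} not in pair {row.pair}"
                )
            r = row.reward
            if r not in (0, 1):
                raise ValueError(
                    f"subject {sid!r} trial {row.trial}: reward must be 0 or 1, got {r}"
                )
            chosen[si, ti] = stim_index[c]
            other[si, ti] = stim_index[partner[c]]
            reward[si, ti] = float(r)
            first[si, ti] = pair.pair_id not in seen_pairs
            seen_pairs.add(pair.pair_id)
            valid[si, ti] = True

    return PackedTrials(
        subject_ids=np.asarray(subjects),
        groups=groups,
        chosen=chosen,
        other=other,
        reward=reward,
        first_of_pair=first,
        valid=valid,
        n_stimuli=len(design.stimuli),
    )


def _log_expit(z):
    """log(logistic(z)) computed stably for large |z|."""
    return -np.logaddexp(0.0, -np.asarray(z, dtype=float))


def trialwise_logprob(packed: PackedTrials, theta, model_id: str) -> np.ndarray:
    """Log probability of each observed choice under an evolving agent state.

    ``theta`` holds constrained parameters, shape (n_subjects, k) or (k,)
    broadcast to all subjects.  Returns an (n_subjects, T_max) array with 0.0
    at padded positions.
    """
    fam = get_family(model_id)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = np.broadcast_to(theta, (packed.n_subjects, fam.n_params)).copy()
    if theta.shape != (packed.n_subjects, fam.n_params):
        raise ValueError(
            f"theta shape {theta.shape} does not match "
            f"({packed.n_subjects}, {fam.n_params})"
        )

    n, t_max = packed.chosen.shape
    rows = np.arange(n)
    q = np.zeros((n, packed.n_stimuli))
    ck = np.zeros((n, packed.n_stimuli))
    out = np.zeros((n, t_max))

    a_gain = theta[:, fam.gain_index]
    a_loss = theta[:, fam.loss_index]
    beta = theta[:, fam.index("beta")]
    if fam.has_forgetting:
        phi = theta[:, fam.index("phi")]
    if fam.response == NOISY_SOFTMAX:
        xi = theta[:, fam.index("xi")]
    if fam.has_initial_bias:
        q0 = theta[:, fam.index("q0")]
    if fam.has_kernel:
        a_ck = theta[:, fam.index("alpha_ck")]
        tau = theta[:, fam.index("tau")]

    for t in range(t_max):
        c = packed.chosen[:, t]
        o = packed.other[:, t]
        r = packed.reward[:, t]
        v = packed.valid[:, t]
        dq = q[rows, c] - q[rows, o]

        if fam.response == INVERSE_GAIN:
            z = dq / np.maximum(beta, BETA_FLOOR)
            logp = np.where(dq == 0.0, np.log(0.5), _log_expit(z))
        elif fam.response == SOFTMAX:
            logp = _log_expit(beta * dq)
        elif fam.response == NOISY_SOFTMAX:
            p = (1.0 - xi) * expit(beta * dq) + xi / 2.0
            logp = np.log(p)
        elif fam.response == KERNEL_SOFTMAX:
            z = beta * dq + tau * (ck[rows, c] - ck[rows, o])
            logp = _log_expit(z)
        else:  # pragma: no cover
            raise AssertionError(fam.response)
        out[:, t] = np.where(v, logp, 0.0)

        # state transition (valid trials only)
        if fam.has_initial_bias:
            inject = v & packed.first_of_pair[:, t]
            q[rows, c] = np.where(inject, q0, q[rows, c])
        pe = r - q[rows, c]
        alpha = np.where(pe > 0, a_gain, a_loss)
        q[rows, c] = q[rows, c] + np.where(v, alpha * pe, 0.0)
        if fam.has_forgetting:
            q *= np.where(v, 1.0 - phi, 1.0)[:, None]
        if fam.has_kernel:
            upd_c = a_ck * (1.0 - ck[rows, c])
            upd_o = a_ck * (0.0 - ck[rows, o])
            ck[rows, c] = ck[rows, c] + np.where(v, upd_c, 0.0)
            ck[rows, o] = ck[rows, o] + np.where(v, upd_o, 0.0)
    return out


def sequence_loglik(trials: pd.DataFrame, params, model_id: str, design=None) -> float:
    """Summed log likelihood of one subject's chronologically ordered choices."""
    from .task import default_design

    if design is None:
        design = default_design()
    trials = trials.copy()
    if "subject_id" not in trials.columns:
        trials["subject_id"] = 0
    if trials["subject_id"].nunique() > 1:
        raise ValueError("sequence_loglik expects a single subject's trials")
    packed = pack_trials(trials, design)
    theta = params if isinstance(params, np.ndarray) else params_to_array(model_id, params)
    lp = trialwise_logprob(packed, np.asarray(theta, dtype=float), model_id)
    return float(lp.sum())


# ---------------------------------------------------------------------------
# choice simulation
# ---------------------------------------------------------------------------

def simulate_choices(
    params,
    schedule: pd.DataFrame,
    design: TaskDesign,
    model_id: str,
    seed,
    return_probs: bool = False,
) -> pd.DataFrame:
    """Simulate a full choice/feedback trajectory on a trial schedule.

    Per trial the left stimulus is chosen when a uniform draw falls below its
    computed choice probability; an exact probability tie (both options at 0.5)
    is resolved by a fair coin, matching the generative rule used for the
    posterior predictive simulations.  Deterministic given the seed.
    """
    fam = get_family(model_id)
    theta = params if isinstance(params, np.ndarray) else params_to_array(model_id, params)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (fam.n_params,):
        raise ValueError(f"expected {fam.n_params} parameters for {model_id}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    stim_index = {s: i for i, s in enumerate(design.stimuli)}
    q = np.zeros(len(design.stimuli))
    ck = np.zeros(len(design.stimuli))
    seen_pairs = set()

    a_gain = theta[fam.gain_index]
    a_loss = theta[fam.loss_index]
    beta = theta[fam.index("beta")]
    phi = theta[fam.index("phi")] if fam.has_forgetting else 0.0
    xi = theta[fam.index("xi")] if fam.response == NOISY_SOFTMAX else 0.0
    q0 = theta[fam.index("q0")] if fam.has_initial_bias else 0.0
    a_ck = theta[fam.index("alpha_ck")] if fam.has_kernel else 0.0
    tau = theta[fam.index("tau")] if fam.has_kernel else 0.0

    records = []
    for row in schedule.itertuples(index=False):
        pair = design.pair(int(row.pair))
        left, right = int(row.left), int(row.right)
        li, ri = stim_index[left], stim_index[right]

        if fam.response == INVERSE_GAIN:
            p_left = choice_prob_inverse_gain(q[li], q[ri], beta)
        elif fam.response == SOFTMAX:
            p_left = choice_prob_softmax(q[li], q[ri], beta)
        elif fam.response == NOISY_SOFTMAX:
            p_left = choice_prob_noisy(q[li], q[ri], beta, xi)
        else:
            p_left = choice_prob_ck(q[li], q[ri], ck[li], ck[ri], beta, tau)

        if p_left == 0.5:  # exact tie: fair coin, the stated generative rule
            choose_left = rng.random() < 0.5
        else:
            choose_left = rng.random() < p_left
        chosen = left if choose_left else right
        ci = stim_index[chosen]
        oi = ri if choose_left else li
        reward = sample_feedback(pair, chosen, rng)

        if fam.has_initial_bias and pair.pair_id not in seen_pairs:
            q[ci] = q0
        seen_pairs.add(pair.pair_id)
        pe = reward - q[ci]
        q[ci] += (a_gain if pe > 0 else a_loss) * pe
        if fam.has_forgetting:
            q *= 1.0 - phi
        if fam.has_kernel:
            ck[ci] += a_ck * (1.0 - ck[ci])
            ck[oi] += a_ck * (0.0 - ck[oi])

        rec = {
            "trial": int(row.trial),
            "pair": pair.pair_id,
            "choice": chosen,
            "optimal": int(chosen == pair.stim_better),
            "reward": int(reward),
        }
        if return_probs:
            rec["p_choice"] = p_left if choose_left else 1.0 - p_left
        records.append(rec)
    return pd.DataFrame(records)
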