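"""Independent reference implementations used as test oracles.

Everything here is deliberately naive and scalar (dicts, math.exp, explicit
loops) and written directly from the model definitions, so it shares no code
path with the package's vectorized likelihood core.
"""

import itertools
import math


def _softmax2(a, b):
    ea, eb = math.exp(a), math.exp(b)
    return ea / (ea + eb)


def choice_prob(model_id, q, ck, stim_a, stim_b, theta):
    """Probability of choosing stim_a over stim_b given the current state."""
    qa, qb = q[stim_a], q[stim_b]
    if model_id in ("SWo", "SSo"):
        return _softmax2(qa / theta["beta"], qb / theta["beta"])
    if model_id in ("SSh", "SWh"):
        return _softmax2(qa * theta["beta"], qb * theta["beta"])
    if model_id == "ES":
        base = _softmax2(qa * theta["beta"], qb * theta["beta"])
        return (1.0 - theta["xi"]) * base + theta["xi"] / 2.0
    if model_id == "RLfCK":
        return _softmax2(
            qa * theta["beta"] + ck[stim_a] * theta["tau"],
            qb * theta["beta"] + ck[stim_b] * theta["tau"],
        )
    raise ValueError(model_id)


def step_state(model_id, q, ck, seen_pairs, pair_id, chosen, other, reward, theta):
    """Advance the agent state in place after a choice and its feedback."""
    if model_id == "ES" and pair_id not in seen_pairs:
        q[chosen] = theta["q0"]
    seen_pairs.add(pair_id)
    pe = reward - q[chosen]
    if model_id == "RLfCK":
        alpha = theta["alpha"]
    else:
        alpha = theta["alpha_gain"] if pe > 0 else theta["alpha_loss"]
    q[chosen] += alpha * pe
    if model_id in ("ES", "RLfCK"):
        for s in q:
            q[s] *= 1.0 - theta["phi"]
    if model_id == "RLfCK":
        ck[chosen] += theta["alpha_ck"] * (1.0 - ck[chosen])
        ck[other] += theta["alpha_ck"] * (0.0 - ck[other])


def sequence_probability(model_id, theta, trials, choices):
    """Probability of one complete choice sequence under fixed feedback.

    ``trials`` is a list of dicts with keys pair, stim_a, stim_b and
    reward_if (stimulus -> reward); ``choices`` is a tuple of 0/1 flags
    selecting stim_a (0) or stim_b (1) per trial.
    """
    stimuli = sorted({s for t in trials for s in (t["stim_a"], t["stim_b"])})
    q = {s: 0.0 for s in stimuli}
    ck = {s: 0.0 for s in stimuli}
    seen = set()
    prob = 1.0
    for t, pick in zip(trials, choices):
        p_a = choice_prob(model_id, q, ck, t["stim_a"], t["stim_b"], theta)
        chosen = t["stim_a"] if pick == 0 else t["stim_b"]
        other = t["stim_b"] if pick == 0 else t["stim_a"]
        prob *= p_a if pick == 0 else (1.0 - p_a)
        step_state(
            model_id, q, ck, seen, t["pair"], chosen, other, t["reward_if"][chosen], theta
        )
    return prob


def enumerate_sequences(model_id, theta, trials):
    """All 2^T choice sequences with their probabilities."""
    out = {}
    for choices in itertools.product((0, 1), repeat=len(trials)):
        out[choices] = sequence_probability(model_id, theta, trials, choices)
    return out


# ---------------------------------------------------------------------------
# hierarchical joint density oracle (tiny configurations)
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def normal_logpdf(x, mean, sd):
    return -0.5 * ((x - mean) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


def joint_density_oracle(model_id, trials_by_subject, groups, xs, mu, delta, sigma,
                         mu_sd, delta_sd, sigma_prior, param_names, constrain):
    """Hand-rolled hierarchical joint log density.

    ``delta`` maps group label -> list of offsets (label 0 implicit zero);
    ``sigma_prior(s)`` returns the prior log density of a spread value;
    ``constrain`` maps an unconstrained vector to constrained scale.
    """
    total = 0.0
    k = len(param_names)
    for p in range(k):
        total += normal_logpdf(mu[p], 0.0, mu_sd)
        total += sigma_prior(sigma[p])
        for lab in (25, 50, 75, 100):
            total += normal_logpdf(delta[lab][p], 0.0, delta_sd)
    for sid, trials in trials_by_subject.items():
        g = groups[sid]
        off = [0.0] * k if g == 0 else delta[g]
        for p in range(k):
            total += normal_logpdf(xs[sid][p], mu[p] + off[p], sigma[p])
        theta_vec = constrain(xs[sid])
        theta = dict(zip(param_names, theta_vec))
        stimuli = sorted({s for t in trials for s in (t["stim_a"], t["stim_b"])})
        q = {s: 0.0 for s in stimuli}
        ck = {s: 0.0 for s in stimuli}
        seen = set()
        for t in trials:
            p_a = choice_prob(model_id, q, ck, t["stim_a"], t["stim_b"], theta)
            pick_a = t["chosen"] == t["stim_a"]
            total += math.log(p_a if pick_a else 1.0 - p_a)
            other = t["stim_b"] if pick_a else t["stim_a"]
            step_state(model_id, q, ck, seen, t["pair"], t["chosen"], other, t["reward"], theta)
    return total


# ---------------------------------------------------------------------------
# exact leave-one-out on an enumerable grid-posterior Bernoulli model
# ---------------------------------------------------------------------------

def exact_loo_bernoulli(y, grid, prior_weights):
    """Exact elpd_loo by refitting the grid posterior without each point.

    y: 0/1 observations; grid: candidate success probabilities; prior_weights:
    prior mass per grid point.  Returns (elpd_loo, pointwise list).
    """
    def lik(p, yi):
        return p if yi == 1 else 1.0 - p

    pointwise = []
    for i, yi in enumerate(y):
        post = list(prior_weights)
        for j, p in enumerate(grid):
            for i2, y2 in enumerate(y):
                if i2 != i:
                    post[j] *= lik(p, y2)
        z = sum(post)
        post = [w / z for w in post]
        pred = sum(w * lik(p, yi) for w, p in zip(post, grid))
        pointwise.append(math.log(pred))
    return sum(pointwise), pointwise
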