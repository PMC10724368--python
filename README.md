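# rhinet

A firing-rate network model of bodily self-perception and the rubber hand
illusion (RHI), for computational neuroscientists studying multisensory
integration and body ownership.

The model wires six brain areas — M1 (motor command), V (vision), S1
(proprioception), EBA (body-part vision), TPJ (primary multisensory
integration) and AI (high-level integration and behavioural output) — as
populations of 41 rate neurons with Gaussian angular tuning on a −60°…+60°
grid (3° spacing). Each neuron relaxes toward its drive with a leaky Euler
step,

    V(t+1) = V(t) − C·(V(t) − S(t))            (sensory sheets)
    V(t+1) = V(t) − C·(V(t) − tanh(Σ W·V_pre)) (downstream areas)

with per-area rate constants C = 0.04 (M1, V, S1, EBA), 0.01 (TPJ), 0.15
(AI). The two pathways converging on AI from S1 and EBA are plastic: after
each trial their weights change by the trial integral of a rate-based
Hebbian rule,

    Δw(t) = α·Vi·Vj + β·Vi′·Vj + γ·Vi·Vj′,   α=−0.0035, β=0.35, γ=−0.55,

gated per postsynaptic neuron by a lateral-inhibition factor
`W_inhibit(T+1) = tanh(W_inhibit(T) − (2·arccos(fs)/π)·e^(fn−1)) + 1` that
confines learning to neurons that fire early and persistently (firing
threshold 0.7). Training is unsupervised motor babbling: random movement
angles with congruent visual feedback. Both plastic pathways flip from
excitatory to inhibitory, with vision (EBA→AI) inhibited more strongly
than proprioception (S1→AI) — the learned asymmetry that underlies the
illusion and the ownership judgments.

Seven simulated experiments probe the trained network: proprioceptive
drift versus visual disparity, proprioceptive precision (receptive-field
width σ), appearance replacement (similar/dissimilar hand as reduced
visual gain), visual asynchrony, proprioception-only and vision-only
ownership, and lesions ("disability") of TPJ or AI.

## Worked example

```python
from rhinet import BodyOwnershipModel

res = BodyOwnershipModel().fit(n_trials=500, n_replicates=5, seed=0)
print(res.summary())
```

```
Bodily self-perception model - training summary
================================================
replicates:          5
trials/replicate:    500
neurons/area:        41
receptive sigma:     3 grid steps
seed:                0

plastic pathway   median mean W   min..max over replicates
  S1-AI              -0.1341   -0.1604 .. -0.1249
  EBA-AI             -1.0837   -1.1530 .. -0.9764

sign flip (excitatory -> inhibitory): True
inhibition stronger for vision (|EBA-AI| > |S1-AI|): True
```

Both plastic pathways became inhibitory and vision is inhibited roughly
eight times more strongly than proprioception. The drift experiment then
reads the behavioural decision (preferred angle of the maximally firing
AI neuron) for a hand at 0° and a visual hand displaced by 12°:

```python
curve = res.drift_sweep()          # median over the 5 replicates
print(curve.drift_at(12.0))        # 12.0  -> the illusion: the perceived
                                   # hand is captured by the visual hand
own_p, _ = res.unisensory_experiment("proprioception_only")
own_v, _ = res.unisensory_experiment("vision_only")
print(own_p, own_v)                # True False -> a moving hand that is
                                   # only seen is not judged one's own
```

At small disparities the decoded drift follows the visual hand (drift
12° at disparity 12°); a 500 ms visual delay or a dissimilar visual hand
abolishes the drift at every disparity.

The same experiments are available from a shell:

```
rhinet train --seed 0
rhinet drift --seed 0 --out out/drift
rhinet unisensory --seed 0 --n-trials 200 --n-replicates 3
rhinet disability --target TPJ --severity 1.0 --out out/lesion
rhinet report --seed 0 --out out/full
```

Each command writes tidy CSV curves, PNG figures and a JSON manifest.

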