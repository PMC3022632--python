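"""Combine heterogeneous evidence with the Dempster-Shafer engine.

Shows how credibilities in (-1, 1) become mass functions, how the
orthogonal sum pools agreeing and conflicting evidence, and how a source's
credibility learns from user feedback.
"""

from credence import belief
from credence.model import SourceRegistry

# Two neutral default credibilities (0.5 each) already yield combined
# belief 0.75: independent half-trusted witnesses corroborate each other.
print("two defaults combined:", belief.combined_credibility([0.5, 0.5]))

# Adding a third agreeing witness pushes belief to 1 - 0.5^3.
print("three defaults combined:", belief.combined_credibility([0.5, 0.5, 0.5]))

# Disagreement: strong belief against strong disbelief renormalises to 4/9
# each, with the rest staying uncertain.
m_for = belief.credibility_to_mass(0.8)
m_against = belief.credibility_to_mass(-0.8)
m = belief.combine_masses(m_for, m_against)
print(f"0.8 vs -0.8 -> m_T={m.m_t:.4f} m_F={m.m_f:.4f} m_U={m.m_u:.4f}")
print("conflict log K:", round(belief.conflict(m_for, m_against), 4))

# Partition a score axis: two well-separated clusters of -log10(p) scores
# get split automatically (model size chosen by BIC).
import numpy as np

rng = np.random.default_rng(1)
scores = np.concatenate([rng.normal(1, 0.1, 50), rng.normal(10, 0.1, 50)])
scheme = belief.fit_partitions(scores, "auto", seed=1)
print("partitions:", scheme.k, "boundary:", round(scheme.boundaries[0], 2))

# Feedback learning: the strongest-positive radio position moves a neutral
# source up by its learning rate, 0.030.
reg = SourceRegistry({"mimi": 0.5})
belief.update_source_credibility(reg, "mimi", 1)
print("source credibility after strongest-positive feedback:", reg.get("mimi"))
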