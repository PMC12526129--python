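"""Core-corona ordering in the amphiphile micelle toy.

Relaxes a box of two-bead amphiphiles (sticky UA tail, charged CG head)
with Langevin dynamics and measures the radial ordering statistic of the
largest cluster: mean head distance from the cluster centre of mass
minus mean tail distance.  Positive values mean the charged heads form
a corona around a hydrophobic core; the zero-charge symmetric control
shows no ordering.
"""

from hybridff.fixtures import micelle_ordering_run

ordered = micelle_ordering_run(seed=0)
control = micelle_ordering_run(seed=0, head_charge=0.0, head_epsilon=6.0)

print(f"charged heads + sticky tails: ordering = {ordered:+.3f} nm  (heads peripheral)")
print(f"symmetric control:            ordering = {control:+.3f} nm  (no structure)")
# The charged corona is what raises the activation barrier for cluster
# fusion, turning diffusion-limited coagulation into reaction-limited
# growth.
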