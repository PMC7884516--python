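"""Recovery study: how well each method reads back known torsion.

Generates phantoms spanning -10 to 50 degrees of construction torsion with
CT-scale vertex noise (sd 0.3 mm, on the order of a 0.4 mm in-plane
resolution), measures all four methods, and tabulates the recovery error of
each method against its own construction ground truth. Errors of a degree
or less mean the pipeline reproduces its defining geometry; they say
nothing about agreement BETWEEN methods, which measure different axes.
"""

from tibtorsion import generate_phantom, ground_truth_table
from tibtorsion.phantom import torsion_family_spec

specs = [
    torsion_family_spec(tau, noise_sd=0.3, seed=10 + i)
    for i, tau in enumerate((-10.0, 10.0, 30.0, 50.0))
]
table = ground_truth_table(specs, measure=True, seed=1)
print(table.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
print(
    "\nworst recovery error per method (deg):\n"
    + table.groupby("method")["error_deg"].max().round(2).to_string()
)
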