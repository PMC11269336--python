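"""Confound residualization, VIF screen and cognition-psychopathology screen.

The anatomical block (8 lobular volumes + ICV) and the cognitive block
(4 NIH Toolbox subscales) are Z-scored, residualized on age/sex/site and
re-standardized; the VIF table checks the anatomical block for
multicollinearity (>5 flags a problem) and the pairwise screen shows that
the cognitive subscales are only weakly inter-correlated and unrelated to
psychopathology severity.
"""

import numpy as np

from neurocca import compute_vif, generate_cohort, hbn_like_spec, make_blocks, pairwise_screen

table = generate_cohort(hbn_like_spec(latent_corrs=(0.25, 0.18), seed=1))
blocks = make_blocks(table)

age = table["age"] - table["age"].mean()
print("max |corr(residualized column, age)|:",
      f"{np.abs(age @ blocks.X / len(table)).max():.2e} (orthogonal by construction)")

print("\nVIF of the anatomical block (values > 5 would flag multicollinearity):")
print(compute_vif(blocks.X, names=blocks.x_names).round(2))

print("\npairwise screen (Pearson r with magnitude labels):")
print(pairwise_screen(table).round(3).to_string(index=False))
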