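"""Recover growth rates and interactions from noiseless day pairs.

Samples a ground-truth 4-genus model, generates 100 one-step composition
pairs from random starts, refits the model, and compares the recovered
coefficients with the truth. On noiseless data the fit is essentially
exact because the objective's global minimum is zero.
"""

import numpy as np

from nednsim import SyntheticSpec, fit, objective_L, sample_params
from nednsim.synthetic import excitation_pairs

spec = SyntheticSpec(k=4, seed=20)
truth = sample_params(spec)
data = excitation_pairs(truth, n_pairs=100, seed=21)

result = fit(data, model="nedn", seed=22)

print(f"objective at truth:    {objective_L(truth, data, 'nedn'):.3e}")
print(f"objective at estimate: {result.objective_value:.3e} "
      f"({result.n_evaluations} evaluations, converged={result.converged})")
print(f"max |alpha error|:     {np.max(np.abs(result.params.alpha - truth.alpha)):.2e}")
print(f"max |beta error|:      {np.max(np.abs(result.params.beta - truth.beta)):.2e}")
print("\ntrue alpha:     ", np.round(truth.alpha, 4))
print("recovered alpha:", np.round(result.params.alpha, 4))
print(
    "\nBoth objectives are ~0 and every coefficient is recovered to within\n"
    "numerical tolerance: with noiseless pairs whose community totals vary\n"
    "below 1, the 20 free parameters are fully identified."
)
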