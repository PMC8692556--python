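"""Fit both solvate-complex (cluster) solubility models.

Dissolution is modelled as A + kappa*B <=> AB_kappa with a Gibbs-energy
change dF(T); the three-parameter variant uses dF = a' - b'T, the
four-parameter extension dF = a'' + b''*T*ln(T) + c''*T.  The richer
temperature law nests the linear one, so its AARD can only improve.
"""

from sccosol import cluster, data, eos

ds = data.load_clemastine_dataset()
clem, co2 = data.load_clemastine(), data.load_co2()

# complex-solvent binary corrections inherited from the EoS regression
inter = eos.fit_eos(ds, clem, co2, mode="t_independent", seed=42).interaction
fits = cluster.fit_cluster_both(ds, clem, co2, seed=42, inter=inter)

for name, fr in fits.items():
    kappa = fr.params[0]
    print(f"{name:5s}: AARD={fr.aard_percent:5.2f}%  kappa={kappa:.3f}  "
          f"dF coefficients={[f'{p:.4g}' for p in fr.params[1:]]}")

params = cluster.NewClusterParams(*fits["new"].params)
dH, dS = cluster.reaction_thermo(params, 323.0)
print(f"\ncomplex formation at 323 K: dH={dH/1000:+.2f} kJ/mol, "
      f"dS={dS:+.1f} J/mol/K")
print(
    "\nAARD is the mean relative deviation over the 24 measurements; the "
    "four-parameter law fits at least as well as the nested linear one."
)
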