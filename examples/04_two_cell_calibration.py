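"""Reduced two-cell experiment: when does a spring pull two cells apart?

Two 6x6 cells joined by one focal-point-plasticity link are simulated
over a grid of (target distance D, cell-matrix contact energy CM,
spring strength lambda).  Separation (no shared contact edge by the end)
maps the lambda needed to overcome adhesion; the printed coefficients
are a least-squares plane fit to the minimal separating lambda surface.
"""

from cleftsim import two_cell_calibration

df, coefs = two_cell_calibration(D_grid=(12.0, 18.0, 24.0),
                                 CM_grid=(1.0, 3.0, 5.0),
                                 lambda_grid=(0.0, 2.0, 10.0, 25.0),
                                 mcs=600, cc=10.0, seed=0)
frac = df.groupby("lam")["separated"].mean()
print("separation fraction by lambda:")
print(frac.to_string())
print(f"lambda*(D, CM) ~ {coefs[0]:.2f} + {coefs[1]:.2f} D "
      f"+ {coefs[2]:.2f} CM + {coefs[3]:.3f} D*CM")
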