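# Baseline hypoxia-recovery experiment.
# Every key shown here equals the built-in default: an empty file runs the
# identical simulation.  Units: lengths mm, times s, concentrations mM.

[physics]
sigma = 0.03       # blood volume fraction (-)
alpha = 2.2e-3     # blood oxygen diffusivity (mm^2/s)
beta = 2.4e-3      # tissue oxygen diffusivity (mm^2/s)
a = 39.0           # blood-tissue exchange rate (1/s)
b = 9.2            # tetramer hemoglobin concentration (mM)
psi_H = 3.6e-2     # plasma concentration at 50% Hb saturation (mM)
r = 2.73           # Hill exponent (-)
mu0 = 0.08         # maximal consumption rate (mM/s)
theta50 = 5e-5     # half-saturation tissue concentration (mM)

[geometry]
side = 1.8         # square side (mm); area 3.24 mm^2
n_inlets = 32      # arteriolar ends
n_outlets = 32     # venular ends
hole_radius = 0.03 # capillary-ostium scale (mm)
layout = "checkerboard"  # or "jittered" (uses seed)
seed = 0

[stokes]
enabled = true
edge_velocity = [0.0, 0.6]  # drift on the outer square (mm/s)
inlet_speed = 3.4           # normal inflow on inlet rims (mm/s)
outlet_speed = 1.7          # normal outflow on outlet rims (mm/s)
penalty = 1e-6              # pressure penalty (absorbs net-flux imbalance)
stabilization = 0.05        # Brezzi-Pitkaranta coefficient

[numerics]
n_edge_segments = 60  # boundary segments per square side
n_hole_segments = 8   # boundary segments per hole
dt = 0.25             # time step (s)
n_picard = 20         # nonlinear sweeps per step
t_final = 10.0        # horizon (s)
phi_max = 12.0        # inverse-Hill table range (mM)
n_knots = 800         # inverse-Hill table knots

[boundary]
gamma_multiplier = 1000.0  # gamma = 1000 * alpha (mm/s)
delta_multiplier = 1000.0  # delta = 1000 * beta (mm/s)
[boundary.phi_b]           # ambient blood oxygen per boundary class (mM)
inlet = 9.2
outlet = 8.2
edge = 8.2                 # outer edges carry the outlet value

[initial]
phi0 = 4.0    # hypoxic blood oxygen (mM)
theta0 = 0.01 # hypoxic tissue oxygen (mM)

[output]
directory = "out"
snapshot_every = 1
figure_times = [1.0, 2.0, 3.0, 7.0]  # always-exported snapshot instants
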