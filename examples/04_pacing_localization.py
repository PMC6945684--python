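"""Localise an ectopic pacing site from noisy body-surface potentials.

Simulates pacing at one node, reconstructs the depolarisation sequence,
derives activation-time maps (frame of steepest upstroke per node), and
compares the estimated pacing origin (earliest activated node) with the
true one.
"""

from ecgitv import (
    SolverParams,
    activation_time_map,
    add_noise,
    build_heart_mesh,
    build_lead_field,
    build_trajectory_graph,
    forward_project,
    localization_error,
    simulate_pacing,
    solve_graph_tv,
    tikhonov,
)
from ecgitv.experiments import ExperimentConfig, tune_lambda, tune_mu
from ecgitv.phantom import TMPSequence

mesh = build_heart_mesh(n_nodes=200, seed=1)
lead_field = build_lead_field(mesh)
truth = simulate_pacing(mesh, pacing_node=10, velocity=0.6, t=180)
clean = forward_project(lead_field, truth)
noisy = add_noise(clean, snr_db=20.0, seed=4)

# tune on a held-out noise realization, evaluate on seed 4
cfg = ExperimentConfig(n_nodes=200)
Phi_tune = add_noise(clean, snr_db=20.0, seed=5).Phi
lam = tune_lambda(lead_field.H, Phi_tune, mesh, truth.U)
mu = tune_mu("graphtv", lead_field.H, Phi_tune, mesh, truth.U, cfg, lam=lam)

U_tik = tikhonov(lead_field.H, noisy.Phi, lam, mesh.surface_laplacian)
graph = build_trajectory_graph(U_tik, k=5)
U_gtv = solve_graph_tv(lead_field.H, noisy.Phi, graph,
                       SolverParams(mu=mu), U_init=U_tik).U_hat

at_true = activation_time_map(truth)
for name, U in [("tikhonov", U_tik), ("graphtv", U_gtv)]:
    at = activation_time_map(TMPSequence(U=U))
    err = localization_error(at, at_true, mesh)
    print(f"{name:9s} pacing-site localization error = {err:.1f} mm")
# the error is the distance between the earliest-activated node of the
# reconstruction and of the truth; graph TV usually lands closer
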