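# photon mass interaction coefficients for dry air (sea level), cm^2/g
# incoherent: exact Klein-Nishina (free electrons); coherent scattering excluded by design
energy_MeV,mu_pe,mu_incoh,mu_pair,muen
1.000000e-02,4.727462e+00,1.925377e-01,0.000000e+00,4.742000e+00
1.100995e-02,3.492600e+00,1.918255e-01,0.000000e+00,3.509614e+00
1.212189e-02,2.580297e+00,1.910493e-01,0.000000e+00,2.597509e+00
1.334614e-02,1.906297e+00,1.902042e-01,0.000000e+00,1.922449e+00
1.469402e-02,1.408353e+00,1.892852e-01,0.000000e+00,1.422829e+00
1.500000e-02,1.319922e+00,1.890782e-01,0.000000e+00,1.334000e+00
1.617804e-02,1.037012e+00,1.882868e-01,0.000000e+00,1.051242e+00
1.781194e-02,7.628886e-01,1.872037e-01,0.000000e+00,7.763348e-01
1.961085e-02,5.612270e-01,1.860301e-01,0.000000e+00,5.733178e-01
2.000000e-02,5.271212e-01,1.857788e-01,0.000000e+00,5.389000e-01
2.159144e-02,4.115788e-01,1.847605e-01,0.000000e+00,4.252325e-01
2.377205e-02,3.015905e-01,1.833891e-01,0.000000e+00,3.157484e-01
2.617290e-02,2.209949e-01,1.819104e-01,0.000000e+00,2.344531e-01
2.881623e-02,1.619373e-01,1.803188e-01,0.000000e+00,1.740887e-01
3.000000e-02,1.421818e-01,1.796182e-01,0.000000e+00,1.537000e-01
3.172651e-02,1.182077e-01,1.786093e-01,0.000000e+00,1.312794e-01
3.493071e-02,8.604916e-02,1.767770e-01,0.000000e+00,1.001039e-01
3.845853e-02,6.263937e-02,1.748176e-01,0.000000e+00,7.633173e-02
4.000000e-02,5.502016e-02,1.739798e-01,0.000000e+00,6.833000e-02
4.234263e-02,4.540059e-02,1.727274e-01,0.000000e+00,5.997608e-02
4.661901e-02,3.280749e-02,1.705034e-01,0.000000e+00,4.811053e-02
5.000000e-02,2.590021e-02,1.687998e-01,0.000000e+00,4.098000e-02
5.132728e-02,2.367861e-02,1.681437e-01,0.000000e+00,3.926043e-02
5.651106e-02,1.703443e-02,1.656473e-01,0.000000e+00,3.354181e-02
6.000000e-02,1.387618e-02,1.640238e-01,0.000000e+00,3.041000e-02
6.221837e-02,1.216610e-02,1.630143e-01,0.000000e+00,2.952582e-02
6.850209e-02,8.585800e-03,1.602464e-01,0.000000e+00,2.730500e-02
7.542043e-02,6.059129e-03,1.573463e-01,0.000000e+00,2.525123e-02
8.000000e-02,4.894049e-03,1.555060e-01,0.000000e+00,2.407000e-02
8.303748e-02,4.204173e-03,1.543184e-01,0.000000e+00,2.393107e-02
9.142382e-02,2.839944e-03,1.511685e-01,0.000000e+00,2.357608e-02
1.000000e-01,1.970321e-03,1.481297e-01,0.000000e+00,2.325000e-02
1.006571e-01,1.915516e-03,1.479040e-01,0.000000e+00,2.327667e-02
1.108230e-01,1.265674e-03,1.445334e-01,0.000000e+00,2.367198e-02
1.220155e-01,8.362912e-04,1.410669e-01,0.000000e+00,2.407400e-02
1.343384e-01,5.525777e-04,1.375155e-01,0.000000e+00,2.448286e-02
1.479058e-01,3.651145e-04,1.338913e-01,0.000000e+00,2.489865e-02
1.500000e-01,3.436620e-04,1.333563e-01,0.000000e+00,2.496000e-02
1.628435e-01,9.308756e-05,1.302070e-01,0.000000e+00,2.545044e-02
1.792898e-01,2.016404e-05,1.264757e-01,0.000000e+00,2.603707e-02
1.973972e-01,4.367807e-06,1.227109e-01,0.000000e+00,2.663723e-02
2.000000e-01,3.546632e-06,1.221965e-01,0.000000e+00,2.672000e-02
2.173332e-01,3.263774e-06,1.189256e-01,0.000000e+00,2.711829e-02
2.392827e-01,2.964387e-06,1.151325e-01,0.000000e+00,2.758678e-02
2.634489e-01,2.692463e-06,1.113437e-01,0.000000e+00,2.806336e-02
2.900559e-01,2.445482e-06,1.075704e-01,0.000000e+00,2.854817e-02
3.000000e-01,2.364422e-06,1.062539e-01,0.000000e+00,2.872000e-02
3.193499e-01,2.221157e-06,1.038226e-01,0.000000e+00,2.888557e-02
3.516026e-01,2.017410e-06,1.001094e-01,0.000000e+00,2.914230e-02
3.871125e-01,1.832352e-06,9.643855e-02,0.000000e+00,2.940131e-02
4.000000e-01,1.773316e-06,9.519997e-02,0.000000e+00,2.949000e-02
4.262088e-01,1.664270e-06,9.281680e-02,0.000000e+00,2.953825e-02
4.692536e-01,1.511606e-06,8.924971e-02,0.000000e+00,2.961155e-02
5.000000e-01,1.418653e-06,8.692896e-02,0.000000e+00,2.966000e-02
5.166457e-01,1.372946e-06,8.574187e-02,0.000000e+00,2.963661e-02
5.688241e-01,1.247005e-06,8.229700e-02,0.000000e+00,2.956799e-02
6.000000e-01,1.182211e-06,8.041482e-02,0.000000e+00,2.953000e-02
6.262722e-01,1.132617e-06,7.891813e-02,0.000000e+00,2.942313e-02
6.895224e-01,1.028721e-06,7.560769e-02,0.000000e+00,2.918462e-02
7.591604e-01,9.343565e-07,7.236769e-02,0.000000e+00,2.894804e-02
8.000000e-01,8.866581e-07,7.063342e-02,0.000000e+00,2.882000e-02
8.358315e-01,8.486477e-07,6.919985e-02,0.000000e+00,2.863498e-02
9.202460e-01,7.708009e-07,6.610568e-02,0.000000e+00,2.823284e-02
1.000000e+00,7.093265e-07,6.349315e-02,0.000000e+00,2.789000e-02
1.013186e+00,7.000951e-07,6.308656e-02,0.000000e+00,2.781625e-02
1.022000e+00,6.940572e-07,6.281849e-02,0.000000e+00,2.776759e-02
1.115512e+00,6.358752e-07,6.014383e-02,4.398764e-05,2.728051e-02
1.170000e+00,6.062619e-07,5.871394e-02,6.961845e-05,2.701881e-02
1.228173e+00,5.775461e-07,5.727880e-02,9.698266e-05,2.675510e-02
1.250000e+00,5.674612e-07,5.676275e-02,1.072500e-04,2.666000e-02
1.330000e+00,5.333282e-07,5.496666e-02,1.256636e-04,2.624899e-02
1.352212e+00,5.245676e-07,5.449274e-02,1.310936e-04,2.614033e-02
1.488778e+00,4.764489e-07,5.178692e-02,1.676123e-04,2.551795e-02
1.500000e+00,4.728843e-07,5.157914e-02,1.708582e-04,2.547000e-02
1.639136e+00,4.327440e-07,4.916256e-02,2.336763e-04,2.482926e-02
1.804680e+00,3.930483e-07,4.662078e-02,3.281751e-04,2.415249e-02
1.986943e+00,3.569938e-07,4.416261e-02,4.608891e-04,2.349416e-02
2.000000e+00,3.546632e-07,4.399833e-02,4.716686e-04,2.345000e-02
2.187614e+00,3.242467e-07,4.178893e-02,5.810631e-04,2.278023e-02
2.408551e+00,2.945034e-07,3.950044e-02,7.268198e-04,2.208280e-02
2.651801e+00,2.674885e-07,3.729760e-02,9.091389e-04,2.140672e-02
2.919619e+00,2.429517e-07,3.518066e-02,1.137192e-03,2.075134e-02
3.000000e+00,2.364422e-07,3.459864e-02,1.211357e-03,2.057000e-02
3.214485e+00,2.206657e-07,3.314959e-02,1.356063e-03,2.010474e-02
3.539131e+00,2.004239e-07,3.120410e-02,1.586946e-03,1.947399e-02
3.896564e+00,1.820390e-07,2.934362e-02,1.857140e-03,1.886302e-02
4.000000e+00,1.773316e-07,2.885162e-02,1.938376e-03,1.870000e-02
4.290095e+00,1.653405e-07,2.756729e-02,2.125230e-03,1.828198e-02
4.723372e+00,1.501737e-07,2.587402e-02,2.411736e-03,1.772273e-02
5.000000e+00,1.418653e-07,2.491092e-02,2.599081e-03,1.740000e-02
5.200407e+00,1.363983e-07,2.426243e-02,2.719307e-03,1.719520e-02
5.725620e+00,1.238864e-07,2.273092e-02,3.037654e-03,1.670391e-02
6.000000e+00,1.182211e-07,2.201425e-02,3.205749e-03,1.647000e-02
6.303877e+00,1.125223e-07,2.127767e-02,3.364496e-03,1.625375e-02
6.940534e+00,1.022006e-07,1.990068e-02,3.696561e-03,1.584073e-02
7.641491e+00,9.282566e-08,1.859777e-02,4.061398e-03,1.543820e-02
8.000000e+00,8.866581e-08,1.800229e-02,4.247712e-03,1.525000e-02
8.413240e+00,8.431073e-08,1.736662e-02,4.430979e-03,1.507740e-02
9.262932e+00,7.657688e-08,1.620480e-02,4.803346e-03,1.475309e-02
1.000000e+01,7.093265e-08,1.532810e-02,5.121901e-03,1.450000e-02
1.019844e+01,6.955246e-08,1.510977e-02,5.191359e-03,1.445143e-02
1.122843e+01,6.317239e-08,1.407894e-02,5.545304e-03,1.421593e-02
1.236244e+01,5.737757e-08,1.310968e-02,5.923381e-03,1.398427e-02
1.361098e+01,5.211430e-08,1.219931e-02,6.327235e-03,1.375639e-02
1.498561e+01,4.733384e-08,1.134517e-02,6.758623e-03,1.353222e-02
1.500000e+01,4.728843e-08,1.133693e-02,6.763071e-03,1.353000e-02
1.649908e+01,4.299189e-08,1.054460e-02,7.136900e-03,1.338946e-02
1.816539e+01,3.904823e-08,9.794973e-03,7.535475e-03,1.324900e-02
2.000000e+01,3.546632e-08,9.093690e-03,7.956310e-03,1.311000e-02
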