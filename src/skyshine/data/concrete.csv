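# photon mass interaction coefficients for ordinary concrete (NIST composition), cm^2/g
# incoherent: exact Klein-Nishina (free electrons); coherent scattering excluded by design
energy_MeV,mu_pe,mu_incoh,mu_pair,muen
1.000000e-02,2.500000e+01,1.964448e-01,0.000000e+00,2.500367e+01
1.100995e-02,1.890500e+01,1.957181e-01,0.000000e+00,1.890901e+01
1.212189e-02,1.429597e+01,1.949262e-01,0.000000e+00,1.430034e+01
1.334614e-02,1.081061e+01,1.940640e-01,0.000000e+00,1.081538e+01
1.469402e-02,8.174987e+00,1.931263e-01,0.000000e+00,8.180181e+00
1.500000e-02,7.700000e+00,1.929151e-01,0.000000e+00,7.705290e+00
1.617804e-02,6.062452e+00,1.921077e-01,0.000000e+00,6.068104e+00
1.781194e-02,4.471973e+00,1.910026e-01,0.000000e+00,4.478116e+00
1.961085e-02,3.298755e+00,1.898052e-01,0.000000e+00,3.305424e+00
2.000000e-02,3.100000e+00,1.895488e-01,0.000000e+00,3.106780e+00
2.159144e-02,2.456921e+00,1.885098e-01,0.000000e+00,2.464151e+00
2.377205e-02,1.834457e+00,1.871106e-01,0.000000e+00,1.842285e+00
2.617290e-02,1.369695e+00,1.856019e-01,0.000000e+00,1.378158e+00
2.881623e-02,1.022682e+00,1.839780e-01,0.000000e+00,1.031816e+00
3.000000e-02,9.050000e-01,1.832632e-01,0.000000e+00,9.144260e-01
3.172651e-02,7.612892e-01,1.822338e-01,0.000000e+00,7.711313e-01
3.493071e-02,5.654815e-01,1.803644e-01,0.000000e+00,5.760667e-01
3.845853e-02,4.200366e-01,1.783652e-01,0.000000e+00,4.313987e-01
4.000000e-02,3.720000e-01,1.775104e-01,0.000000e+00,3.836885e-01
4.234263e-02,3.112900e-01,1.762325e-01,0.000000e+00,3.234602e-01
4.661901e-02,2.303345e-01,1.739634e-01,0.000000e+00,2.433413e-01
5.000000e-02,1.850000e-01,1.722252e-01,0.000000e+00,1.986313e-01
5.132728e-02,1.703049e-01,1.715558e-01,0.000000e+00,1.841729e-01
5.651106e-02,1.256682e-01,1.690087e-01,0.000000e+00,1.404174e-01
6.000000e-02,1.040000e-01,1.673523e-01,0.000000e+00,1.193057e-01
6.221837e-02,9.289367e-02,1.663224e-01,0.000000e+00,1.085388e-01
6.850209e-02,6.886615e-02,1.634982e-01,0.000000e+00,8.541580e-02
7.542043e-02,5.105349e-02,1.605393e-01,0.000000e+00,6.850935e-02
8.000000e-02,4.250000e-02,1.586616e-01,0.000000e+00,6.050871e-02
8.303748e-02,3.774954e-02,1.574499e-01,0.000000e+00,5.610582e-02
9.142382e-02,2.779746e-02,1.542362e-01,0.000000e+00,4.704033e-02
1.000000e-01,2.090000e-02,1.511357e-01,0.000000e+00,4.094924e-02
1.006571e-01,2.047732e-02,1.509054e-01,0.000000e+00,4.058452e-02
1.108230e-01,1.516804e-02,1.474664e-01,0.000000e+00,3.610863e-02
1.220155e-01,1.123533e-02,1.439296e-01,0.000000e+00,3.296965e-02
1.343384e-01,8.322280e-03,1.403061e-01,0.000000e+00,3.080206e-02
1.479058e-01,6.164512e-03,1.366083e-01,0.000000e+00,2.933325e-02
1.500000e-01,5.900000e-03,1.360625e-01,0.000000e+00,2.916421e-02
1.628435e-01,4.590420e-03,1.328492e-01,0.000000e+00,2.838390e-02
1.792898e-01,3.421365e-03,1.290423e-01,0.000000e+00,2.776839e-02
1.973972e-01,2.550036e-03,1.252011e-01,0.000000e+00,2.737329e-02
2.000000e-01,2.450000e-03,1.246762e-01,0.000000e+00,2.733182e-02
2.173332e-01,1.906111e-03,1.213389e-01,0.000000e+00,2.712320e-02
2.392827e-01,1.425436e-03,1.174689e-01,0.000000e+00,2.694997e-02
2.634489e-01,1.065976e-03,1.136032e-01,0.000000e+00,2.680877e-02
2.900559e-01,7.971633e-04,1.097533e-01,0.000000e+00,2.666743e-02
3.000000e-01,7.200000e-04,1.084101e-01,0.000000e+00,2.661333e-02
3.193499e-01,6.034295e-04,1.059295e-01,0.000000e+00,2.650996e-02
3.516026e-01,4.597832e-04,1.021409e-01,0.000000e+00,2.631215e-02
3.871125e-01,3.503319e-04,9.839557e-02,0.000000e+00,2.605997e-02
4.000000e-01,3.193670e-04,9.713186e-02,0.000000e+00,2.596071e-02
4.262088e-01,2.669354e-04,9.470032e-02,0.000000e+00,2.574819e-02
4.692536e-01,2.033915e-04,9.106084e-02,0.000000e+00,2.537444e-02
5.000000e-01,1.700000e-04,8.869300e-02,0.000000e+00,2.509389e-02
5.166457e-01,1.587667e-04,8.748181e-02,0.000000e+00,2.494247e-02
5.688241e-01,1.298776e-04,8.396704e-02,0.000000e+00,2.445452e-02
6.000000e-01,1.161879e-04,8.204667e-02,0.000000e+00,2.415750e-02
6.262722e-01,1.062452e-04,8.051960e-02,0.000000e+00,2.390610e-02
6.895224e-01,8.691291e-05,7.714198e-02,0.000000e+00,2.330276e-02
7.591604e-01,7.109831e-05,7.383624e-02,0.000000e+00,2.265057e-02
8.000000e-01,6.373178e-05,7.206678e-02,0.000000e+00,2.227711e-02
8.358315e-01,5.816132e-05,7.060412e-02,0.000000e+00,2.195595e-02
9.202460e-01,4.757833e-05,6.744715e-02,0.000000e+00,2.122558e-02
1.000000e+00,4.000000e-05,6.478161e-02,0.000000e+00,2.057104e-02
1.013186e+00,3.947943e-05,6.436677e-02,0.000000e+00,2.046674e-02
1.022000e+00,3.913894e-05,6.409326e-02,0.000000e+00,2.039754e-02
1.115512e+00,3.585797e-05,6.136432e-02,6.598145e-05,1.969399e-02
1.170000e+00,3.418803e-05,5.990541e-02,1.044277e-04,1.930927e-02
1.228173e+00,3.256871e-05,5.844115e-02,1.454740e-04,1.891780e-02
1.250000e+00,3.200000e-05,5.791463e-02,1.608751e-04,1.877584e-02
1.330000e+00,3.007519e-05,5.608209e-02,1.884954e-04,1.827070e-02
1.352212e+00,2.958117e-05,5.559856e-02,1.966404e-04,1.813594e-02
1.488778e+00,2.686768e-05,5.283783e-02,2.514184e-04,1.735692e-02
1.500000e+00,2.666667e-05,5.262583e-02,2.562872e-04,1.729654e-02
1.639136e+00,2.440310e-05,5.016021e-02,3.505145e-04,1.660142e-02
1.804680e+00,2.216459e-05,4.756685e-02,4.922626e-04,1.588051e-02
1.986943e+00,2.013143e-05,4.505880e-02,6.913337e-04,1.521101e-02
2.000000e+00,2.000000e-05,4.489118e-02,7.075029e-04,1.516783e-02
2.187614e+00,1.828476e-05,4.263695e-02,8.715946e-04,1.456253e-02
2.408551e+00,1.660750e-05,4.030201e-02,1.090230e-03,1.396655e-02
2.651801e+00,1.508409e-05,3.805448e-02,1.363708e-03,1.343865e-02
2.919619e+00,1.370042e-05,3.589458e-02,1.705788e-03,1.299385e-02
3.000000e+00,1.333333e-05,3.530075e-02,1.817036e-03,1.288570e-02
3.214485e+00,1.244367e-05,3.382229e-02,2.034095e-03,1.258207e-02
3.539131e+00,1.130221e-05,3.183732e-02,2.380419e-03,1.222347e-02
3.896564e+00,1.026546e-05,2.993908e-02,2.785710e-03,1.194847e-02
4.000000e+00,1.000000e-05,2.943711e-02,2.907564e-03,1.188941e-02
4.290095e+00,9.323802e-06,2.812671e-02,3.187845e-03,1.171257e-02
4.723372e+00,8.468526e-06,2.639908e-02,3.617604e-03,1.153783e-02
5.000000e+00,8.000000e-06,2.541643e-02,3.898621e-03,1.147414e-02
5.200407e+00,7.691706e-06,2.475478e-02,4.078961e-03,1.142721e-02
5.725620e+00,6.986143e-06,2.319219e-02,4.556481e-03,1.136779e-02
6.000000e+00,6.666667e-06,2.246098e-02,4.808624e-03,1.136860e-02
6.303877e+00,6.345302e-06,2.170946e-02,5.046745e-03,1.135537e-02
6.940534e+00,5.763245e-06,2.030452e-02,5.544841e-03,1.138424e-02
7.641491e+00,5.234581e-06,1.897517e-02,6.092097e-03,1.148842e-02
8.000000e+00,5.000000e-06,1.836761e-02,6.371568e-03,1.156572e-02
8.413240e+00,4.754411e-06,1.771904e-02,6.646468e-03,1.163076e-02
9.262932e+00,4.318287e-06,1.653364e-02,7.205019e-03,1.180680e-02
1.000000e+01,4.000000e-06,1.563915e-02,7.682851e-03,1.199697e-02
1.019844e+01,3.922169e-06,1.541639e-02,7.787039e-03,1.203201e-02
1.122843e+01,3.562387e-06,1.436464e-02,8.317956e-03,1.223734e-02
1.236244e+01,3.235608e-06,1.337571e-02,8.885071e-03,1.249975e-02
1.361098e+01,2.938805e-06,1.244687e-02,9.490852e-03,1.282071e-02
1.498561e+01,2.669227e-06,1.157540e-02,1.013793e-02,1.320188e-02
1.500000e+01,2.666667e-06,1.156699e-02,1.014461e-02,1.320599e-02
1.649908e+01,2.424378e-06,1.075859e-02,1.070535e-02,1.352898e-02
1.816539e+01,2.201989e-06,9.993741e-03,1.130321e-02,1.390303e-02
2.000000e+01,2.000000e-06,9.278227e-03,1.193447e-02,1.432598e-02
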