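# Synthetic reference-sample PC coordinates for plotting context (non-diagnostic).
sample	population	pc1	pc2
POP_A_00	POP_A	-0.229258	-0.759436
POP_A_01	POP_A	0.041863	-0.579095
POP_A_02	POP_A	-0.200190	0.541337
POP_A_03	POP_A	-0.399491	0.344698
POP_A_04	POP_A	-0.261529	-0.513889
POP_A_05	POP_A	1.129348	0.949696
POP_A_06	POP_A	-1.618953	-1.918963
POP_A_07	POP_A	-0.507182	-0.348418
POP_A_08	POP_A	-0.173151	0.182385
POP_A_09	POP_A	-0.158881	-0.044346
POP_A_10	POP_A	0.440190	0.274187
POP_A_11	POP_A	-0.559713	-1.154327
POP_A_12	POP_A	-0.333001	-0.693208
POP_A_13	POP_A	0.670247	-0.271792
POP_A_14	POP_A	-1.548462	-0.824588
POP_A_15	POP_A	-0.940251	-1.474557
POP_A_16	POP_A	1.039561	0.376362
POP_A_17	POP_A	-0.364180	-0.266028
POP_A_18	POP_A	-0.563125	-1.337975
POP_A_19	POP_A	0.440565	0.853260
POP_B_00	POP_B	-0.370843	-0.218740
POP_B_01	POP_B	-0.300998	-0.352148
POP_B_02	POP_B	0.317286	-0.296876
POP_B_03	POP_B	0.329421	-0.032429
POP_B_04	POP_B	0.242143	-1.184984
POP_B_05	POP_B	0.134619	1.176618
POP_B_06	POP_B	0.210154	1.069130
POP_B_07	POP_B	0.364298	0.056187
POP_B_08	POP_B	0.459572	0.574730
POP_B_09	POP_B	0.373637	0.309601
POP_B_10	POP_B	0.570661	0.347890
POP_B_11	POP_B	0.334211	-0.175750
POP_B_12	POP_B	-0.539370	-1.001371
POP_B_13	POP_B	-0.718262	-0.901480
POP_B_14	POP_B	-1.104979	-0.115540
POP_B_15	POP_B	-0.447505	0.200243
POP_B_16	POP_B	0.278641	-1.157091
POP_B_17	POP_B	0.637852	0.417095
POP_B_18	POP_B	-0.301870	-1.052727
POP_B_19	POP_B	-1.386435	-0.635573
POP_C_00	POP_C	-0.046153	0.050724
POP_C_01	POP_C	0.579300	1.167888
POP_C_02	POP_C	-0.341617	0.330445
POP_C_03	POP_C	0.189850	1.190734
POP_C_04	POP_C	0.629877	1.457339
POP_C_05	POP_C	1.202145	0.679832
POP_C_06	POP_C	0.098599	0.781402
POP_C_07	POP_C	-0.898876	-0.425492
POP_C_08	POP_C	0.257129	0.457721
POP_C_09	POP_C	-0.015026	0.420370
POP_C_10	POP_C	0.753514	0.652666
POP_C_11	POP_C	1.054321	0.409398
POP_C_12	POP_C	-0.818373	0.652591
POP_C_13	POP_C	-0.698565	0.434351
POP_C_14	POP_C	0.847573	0.146555
POP_C_15	POP_C	-0.945694	0.474627
POP_C_16	POP_C	-0.044635	1.588952
POP_C_17	POP_C	0.942655	1.285207
POP_C_18	POP_C	0.205592	-0.242243
POP_C_19	POP_C	-0.847195	-0.820639
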