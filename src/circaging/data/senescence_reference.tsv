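circ_id	cell_type	median_early	median_late	p	expressed
circAFF1	astrocytes	0.58	0.84	0.040	True
circASAP1	astrocytes	1.39	1.22	0.878	True
circATP6V0A1	astrocytes	1.60	1.14	0.229	True
circCDYL	astrocytes	0.71	0.90	0.001	True
circEP300	astrocytes	1.01	1.05	0.329	True
circFNDC3B	astrocytes	0.96	1.38	0.059	True
circFOXO3	astrocytes	0.88	0.89	0.646	True
circMETTL3	astrocytes	0.97	0.69	0.180	True
circMIB1	astrocytes	0.71	1.03	0.008	True
circPLEKHM1	astrocytes	1.05	0.76	0.306	True
circXPO7	astrocytes	1.25	1.54	0.987	True
circZC3H18	astrocytes	1.50	0.88	0.346	True
circAFF1	cardiomyocytes	1.15	1.42	0.357	True
circASAP1	cardiomyocytes	0.74	0.84	0.643	True
circATP6V0A1	cardiomyocytes	0.57	0.41	0.249	True
circCDYL	cardiomyocytes	1.47	1.42	0.855	True
circEP300	cardiomyocytes	1.27	1.10	0.596	True
circFNDC3B	cardiomyocytes	1.03	1.93	0.139	True
circFOXO3	cardiomyocytes	1.00	0.82	0.015	True
circMETTL3	cardiomyocytes	0.88	0.66	0.186	True
circMIB1	cardiomyocytes	0.96	1.16	0.129	True
circPLEKHM1	cardiomyocytes	0.85	0.82	0.983	True
circXPO7	cardiomyocytes	0.89	1.32	0.227	True
circZC3H18	cardiomyocytes	0.83	0.85	0.862	True
circAFF1	endothelial_cells	0.94	1.07	0.548	True
circASAP1	endothelial_cells	1.03	1.69	0.467	True
circATP6V0A1	endothelial_cells	0.37	0.48	0.821	True
circCDYL	endothelial_cells	0.90	0.89	0.942	True
circEP300	endothelial_cells	0.99	0.58	0.128	True
circFNDC3B	endothelial_cells	1.74	7.84	0.080	True
circFOXO3	endothelial_cells	0.38	0.14	0.275	True
circMETTL3	endothelial_cells	1.02	0.39	0.072	True
circMIB1	endothelial_cells	1.36	1.11	0.640	True
circPLEKHM1	endothelial_cells	1.02	1.47	0.380	True
circXPO7	endothelial_cells	0.97	0.87	0.620	True
circZC3H18	endothelial_cells	1.02	1.51	0.047	True
circAFF1	fibroblasts	1.06	0.58	0.003	True
circASAP1	fibroblasts	0.51	1.05	0.196	True
circATP6V0A1	fibroblasts	1.39	1.10	0.375	True
circCDYL	fibroblasts	1.13	0.90	0.640	True
circEP300	fibroblasts	0.96	0.38	0.023	True
circFNDC3B	fibroblasts	0.50	0.90	0.182	True
circFOXO3	fibroblasts	1.91	1.60	0.025	True
circMETTL3	fibroblasts	1.23	1.39	0.030	True
circMIB1	fibroblasts	1.20	0.85	0.072	True
circPLEKHM1	fibroblasts	1.00	0.84	0.716	True
circXPO7	fibroblasts	1.03	0.57	0.645	True
circZC3H18	fibroblasts	0.93	0.74	0.432	True
circBCL11B	astrocytes				False
circDEF6	astrocytes				False
circITGAX	astrocytes				False
circBCL11B	cardiomyocytes				False
circDEF6	cardiomyocytes				False
circITGAX	cardiomyocytes				False
circBCL11B	endothelial_cells				False
circDEF6	endothelial_cells				False
circITGAX	endothelial_cells				False
circBCL11B	fibroblasts				False
circDEF6	fibroblasts				False
circITGAX	fibroblasts				False
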